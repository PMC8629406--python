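# ovhet

Multi-region, multi-timepoint heterogeneity analysis for epithelial ovarian
cancer (EOC) targeted-panel sequencing.

Stage III/IV EOC is a systemic disease: tumor deposits grow in the ovary and
at multiple pelvic–peritoneal sites, and relapse emerges after chemotherapy.
Deep targeted sequencing of multiple biopsies per patient (a 65-gene panel at
~2500× coverage, with a matched blood sample per patient) makes it possible
to ask how much of each lesion's mutational repertoire is private, which
mutations are founder events shared across lesions, and whether relapsed
disease descends from a clone already present at primary surgery. `ovhet`
implements that analysis as a reusable pipeline, together with a forward
clonal-evolution simulator that generates cohorts with known ground truth so
every stage can be validated at desk scale.

## What it computes

Given per-biopsy somatic calls (VCF or TSV), a sample sheet and a gene panel:

1. **Somatic filtering** (`ovhet.somatic_filter`) — harmonizes two callers'
   outputs per sample (union or intersection), then keeps a tumor call iff
   depth ≥ 200×, allelic fraction AF > 1% (strict), and the locus is not
   germline in the matched blood (blood AF > 2% at adequate blood coverage).
   Every rejection carries one primary reason (germline → depth → af).
2. **Variant classes and sharing** (`ovhet.classify`) — effects
   (non-synonymous / synonymous / indel < 50 bp / VUS); cohort-scope *shared*
   loci (≥1 ovary and ≥1 synchronous lesion, not necessarily the same
   patient); patient-scope *concordant* vs *private* loci; a compartment ×
   effect count table with totals.
3. **Heterogeneity statistics** (`ovhet.hetstats`) — per-sample mutational
   burden, per-gene and per-pathway counts with an ovary-vs-synchronous
   two-proportion test, patient × gene concordance matrices, and leaf-pair
   similarity triples (concordant % / private % / wild-type % over the
   patient's somatic-locus universe).
4. **Clustering and phylogenies** (`ovhet.cluster_phylo`) — hierarchical
   clustering of the samples × loci AF matrix (synonymous loci excluded by
   default), and per-patient neighbor-joining trees on AF distances, rooted
   on an unrelated control cell-line profile (OVCAR-8-style outgroup). For a
   pair of samples with AF vectors $x, y$ over the locus universe the
   distance is $d(x,y) = \lVert x - y\rVert_2$ (or $\ell_1$), and NJ joins
   the pair minimizing $Q_{ij} = (n-2)\,d_{ij} - \sum_k d_{ik} - \sum_k d_{jk}$.
5. **Substitution spectra** (`ovhet.spectrum`) — six pyrimidine-folded SNV
   classes (C>A, C>G, C>T, T>A, T>C, T>G), pooled pre- vs post-chemotherapy,
   compared with a chi-squared homogeneity test.
6. **Simulation** (`ovhet.clonesim`) — branched subclone trees (trunk, an
   ovarian and a peritoneal lineage, one terminal subclone per lesion,
   relapse descending from one primary subclone), expected AF =
   purity × CCF × 0.5, negative-binomial depth, binomial alt reads with
   per-base error, germline hets in blood, full ground truth, plus recovery
   instrumentation (sensitivity/specificity, Robinson-Foulds distance to the
   true lineage tree, concordance error vs the true trunk fraction).

## Worked example

Run the whole pipeline on a one-patient simulated cohort (two ovarian
lesions, omentum, peritoneum, one relapse, plus blood and the unrelated
control):

```python
from ovhet.pipeline import RunConfig, run_pipeline
from ovhet.clonesim import SimulationConfig

cfg = RunConfig(out_dir="demo", seed=7, simulate=True,
                sim=SimulationConfig(n_patients=1))
manifest = run_pipeline(cfg)
```

The run writes ten TSV tables, a Newick tree per patient, the effective
config and a manifest into `demo/`. Selected output from this exact run:

```text
filter:    766 raw calls -> 237 passing, 377 rejected (germline 150, af 227)
classify:  89 distinct somatic loci; 12 shared (13.5%)
```

`demo/category_table.tsv` (compartment × effect counts; shared loci are
counted once in the shared row, not in the exclusive rows):

```text
            non_synonymous  synonymous  indel  vus  total
ovary                   14           5      2   22     43
synchronous             12           3      2   17     34
shared                   3           1      1    7     12
total                   29           9      5   46     89
```

`demo/similarity.tsv` (cherries of the patient tree; percentages over the
patient's 102-locus universe):

```text
sample_a    sample_b       Concordant mutations  Private mutations  Wt
20001-L-OV  20001-R-OV     24.51%                29.41%             46.08%
20001-OM    20001-OM-2ME   35.29%                12.75%             51.96%
```

Reading: the two ovarian lesions agree only on trunk and ovarian-lineage
mutations (24.5% of the patient's loci) and each carries its own private
set; the relapse (`-2ME`) pairs with the omental lesion it descends from.
The tree in `demo/trees/20001.nwk` shows the same structure, rooted on the
control:

```text
(OVCAR-8,((20001-L-OV,20001-R-OV),(20001-PE,(20001-OM,20001-OM-2ME))));
```

The same analyses are available from the shell:

```bash
ovhet simulate --seed 7 --out sim_dir          # write a simulated bundle
ovhet run --config cfg.yaml --out results_dir  # run on any bundle
ovhet filter variants.tsv samples.tsv --out passing.tsv --audit audit.tsv
```

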