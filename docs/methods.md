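# Methods

## The analysis model

`ovhet` treats a patient as a set of tumor biopsies (ovary, synchronous
pelvic–peritoneal lesions at primary surgery, metachronous lesions at second
or third surgery) plus one matched blood sample, sequenced on a targeted
gene panel at deep coverage. All downstream statistics operate on somatic
variant calls — (chrom, pos, ref, alt) loci with read counts and allelic
fractions (AF) — never on reads.

**Locus identity.** Two calls are "the same mutation" iff chrom, pos, ref
and alt all agree. This allele-aware reading is deliberately conservative:
two different substitutions at one site never produce spurious concordance.
`Locus.site_key()` exposes the looser position-only key for users who want
it.

**Somatic filter.** A tumor call passes iff depth ≥ `min_depth` (default
200, inclusive — "a minimum coverage of 200-fold" reads naturally as ≥),
AF > `min_af` (default 1%, strict — "greater than 1%"), and the locus is not
germline. Germline status comes from the matched blood: blood AF >
`germline_max_af_in_blood` (default 2%) with blood depth ≥ 50×. The 2%
cutoff is a conventional matched-normal threshold, far below the ~50%
expectation for a heterozygous germline variant yet above the sequencing
error floor at 2500×; it is configurable because panels with lower blood
coverage may need a looser value. Loci whose blood coverage is below 50× are
retained but flagged `blood_low_coverage` — germline status simply cannot be
decided there, and silently dropping them would bias burden downward.
Rejection reasons are assigned in the fixed order germline → depth → af so
audit summaries are deterministic; the precedence is a reporting choice
only, the passing set does not depend on it.

**Caller harmonization.** Calls from two callers are merged by locus. The
default is the union (maximizing sensitivity at 2500×, where both callers'
false-positive contributions are controlled by the depth/AF/germline
filters), with provenance tags so a consensus (intersection) view can be
recovered by post-filtering. When both callers report a locus, counts are
taken from the caller with the higher depth.

**Effect classes.** Four mutually exclusive classes: indel (length-changing,
< 50 bp; longer events are out of panel scope), synonymous and
non-synonymous (substitutions with a codon annotation, translated with the
standard genetic code), and VUS. Without an annotation database a
substitution carrying no codon annotation is a VUS; an explicit `effect`
column in the input (e.g. from the simulator or a pre-annotated VCF) is
respected as-is. This keeps the package free of any bundled annotation
source.

**Sharing partitions.** Two scopes, matching how multi-region studies report
them:

* *shared* (cohort scope): the locus is somatic in ≥ 1 ovary sample and ≥ 1
  synchronous (non-ovarian primary-surgery) sample anywhere in the cohort;
* *concordant* (patient scope): somatic in the patient's ovary and ≥ 1 of
  that same patient's synchronous lesions; otherwise *private*. Loci
  recurring in ≥ 2 synchronous lesions with no ovarian support are labeled
  `synchronous_recurrent` and reported separately — forcing them into the
  concordant/private binary would corrupt concordance percentages. Loci
  recurring only across multiple ovary samples of one patient are counted
  as private (they satisfy neither definition); this is a documented edge of
  the three-way partition.

**Category table.** Compartment rows (ovary-exclusive,
synchronous-exclusive, shared) are mutually exclusive: a shared locus is
counted once, in the shared row only. Non-shared loci are deduplicated
within a patient's compartment but counted per patient across patients (a
recurrent locus in two patients' ovaries contributes two ovary counts).
Whether cohort-level tables should also deduplicate across patients is
genuinely ambiguous in the field's reporting conventions; per-patient
counting is the package's documented choice because it is consistent with
per-patient burden means.

**Leaf-pair similarity.** For a biopsy pair (A, B) of one patient, the
universe is every locus passing filters in ≥ 1 sample of that patient.
Concordant = called in both, private = called in exactly one, wild type =
called in neither (somatic elsewhere in the patient); the three percentages
sum to 100 by construction (wild type absorbs the ≤ 0.01 rounding residual).
The universe choice makes the triple a well-defined finite partition; an
alternative universe (all cohort-variant panel positions) would only scale
all percentages down uniformly. Both SNVs and indels are included.

**AF matrix, clustering, trees.** The samples × loci AF matrix uses 0 where
a sample has no call — with matched-normal filtering at 2500×, absence of a
call is strong evidence of absence, and imputation would invent signal.
Synonymous loci are excluded from clustering and trees by default (they
carry no selective information and the reference analyses exclude them).
Clustering is agglomerative (euclidean metric, average linkage by default —
no metric is canonical here, and these defaults are the common choice for AF
heatmaps), with rows pre-sorted by sample id so tied merges resolve
identically regardless of input order. Patient trees are neighbor-joining on
pairwise AF distances. NJ was chosen as the tree method because it is the
standard distance-based reconstruction, exactly recovers additive matrices,
is deterministic, and supports outgroup rooting; ties in the Q criterion are
broken by the smallest (row, column) index pair. Negative NJ branch lengths
(possible on non-additive input) are clamped to zero with the deficit moved
to the sibling branch, preserving the cherry's total path length. The tree
is rooted on the edge leading to a designated unrelated control — an
independent cell-line-like AF profile, distant from every patient sample, so
the root placement is stable.

**Spectra.** SNVs are folded to the pyrimidine-referenced convention
standard in mutational-signature work (G>A → C>T, etc.). Pre- vs
post-chemotherapy spectra (primary vs second/third surgery, pooled across
patients by default) are compared with a chi-squared homogeneity test on the
6 × 2 table, without continuity correction (so identical spectra give
statistic 0, p = 1); classes empty in both arms are dropped with the degrees
of freedom adjusted.

## The simulator

`clonesim` generates what the statistics consume, with known truth:

* **Subclone tree.** A founder clone (trunk) with a fixed number of
  mutations (default 12); two lineage stems — ovarian and peritoneal — and
  one terminal subclone per biopsied lesion, each edge carrying
  Poisson-distributed private mutations (default mean 15 per edge). The
  defaults put the trunk at roughly 10% of a patient's mutations, matching
  the early-divergence, private-mutation-dominated regime these cohorts
  show. Relapse biopsies descend from exactly one primary lesion's dominant
  subclone and add further private mutations (same spectrum; a C>T
  enrichment multiplier is available but off by default).
* **Mutations.** Assigned to the 65-gene panel proportionally to coding
  length; effect classes drawn with probabilities 416:106:45:564 /1131
  (the cohort-wide class split of deep targeted EOC panels); substitution
  classes from a C>T-dominant spectrum (C>A 8%, C>G 8%, C>T 40%, T>A 8%,
  T>C 24%, T>G 12%). Loci are unique across a cohort so one variant never
  carries two effect labels.
* **Reads.** A biopsy is its terminal subclone at purity ρ (default 0.7, a
  typical macrodissected EOC biopsy; 0.6 in the recovery suites as the
  stated lower bound). Expected AF = ρ × CCF × 0.5 under the heterozygous
  diploid assumption. Depth ~ negative binomial (mean 2500, size 50 —
  overdispersed as amplicon panels are); alt reads ~ binomial(depth,
  AF + e/3) with per-base error e = 1e-3 spread uniformly over the three
  non-reference bases. Blood carries 30 germline heterozygous loci at AF 0.5
  and error-only reads at somatic loci; 20 error-only positions per patient
  provide false-positive candidates. A tumor row is emitted only when at
  least one alt read is observed (a caller reports nothing otherwise);
  blood rows are always emitted so the germline filter can see blood depth.
* **Cohort layout.** Defaults: two ovarian + two synchronous lesions and
  one relapse per patient. `reference_cohort_layout(19)` reproduces the reference
  cohort shape: 19 patients, 71 tumor biopsies (21 ovary, 24 synchronous,
  26 follow-up including one bilateral, third-surgery patient), 19 bloods.
* **What it does not model.** Copy number, LOH and methylation (AF is used
  only ordinally/metrically downstream, and copy number would add
  unidentifiable parameters — noted as the main extension point); subclonal
  mixtures within a biopsy (compositions are pure by construction, though
  the truth container supports mixtures); read-level artifacts (strand
  bias, mapping error); germline variants shared between patients. Passing
  tests therefore demonstrate correctness of the statistics under the
  branched-evolution, diploid-heterozygous model — not robustness to
  copy-number-distorted AFs in real tumors.

## Recovery instrumentation and problem sizes

`truth_compare` measures, per simulated patient: somatic-call sensitivity
over true mutations with expected AF ≥ 0.05 (at 2500× such a locus yields
~125 alt reads; the binomial tail below the 1% AF cutoff is ~1e-30, so the
design target ≥ 0.99 has essentially no sampling slack), specificity over
germline and error-only loci, the unrooted Robinson–Foulds distance between
the inferred tree (outgroup removed) and the true lineage tree restricted to
sampled biopsies, and the absolute error of the concordant percentage
against the true trunk fraction. The recovery suites run 50 replicate
patients and the NJ suite 100 random additive matrices of 6–10 taxa — sizes
at which every quantity is stable to well below its acceptance margin while
the whole test suite stays interactive (a few seconds).

## Numerical and determinism notes

* AF is stored as a fraction in [0, 1]; user-facing tables print percent to
  2 decimals.
* TSV round trips preserve AF to full precision (written via `repr`).
* All randomness flows through a single `numpy` Generator seeded from the
  run seed; iteration orders are sorted everywhere, so identical config +
  seed reproduce byte-identical output bundles (hash-checked in the tests).
* Degenerate inputs fail loudly: empty locus universes, missing matched
  blood, < 3 taxa for NJ, zero-SNV spectra, NaN in AF matrices.

## Known limitations

* Concordance and category tables consider primary-surgery samples only;
  relapse-only loci appear in burden, spectra, trees and similarity but not
  in the concordant/private partition.
* The two-proportion pathway test treats mutation counts as independent
  draws, ignoring patient-level clustering; at desk-scale counts this is a
  screening statistic, not a confirmatory model.
* The VUS class is an annotation-availability label, not a functional
  prediction.
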