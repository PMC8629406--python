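"""Forward simulator of multi-lesion, multi-timepoint epithelial ovarian
cancer cohorts with ground truth.

The generative model mirrors the structure of deep targeted-panel studies of
EOC heterogeneity:

* each patient carries a branched subclone tree: a founder clone (trunk)
  whose mutations are present in every tumor cell, two lineage stems — one
  giving rise to the ovarian lesions, one to the pelvic–peritoneal
  (synchronous) lesions — and one terminal subclone per biopsied lesion;
* trunk mutations are fixed in count; every other edge receives a Poisson
  number of private mutations, assigned to panel genes proportionally to
  coding length, with effect classes and substitution classes drawn from
  configurable proportions;
* a biopsy is a pure sample of its lesion's terminal subclone diluted by
  normal tissue (purity), so the expected allelic fraction of a mutation is
  ``purity × CCF × 0.5`` under the heterozygous diploid assumption;
* sequencing depth is negative-binomial around the panel's mean depth
  (overdispersed, as amplicon panels are) and alt reads are binomial with a
  per-base substitution error spread uniformly over the three non-reference
  bases (+error/3 on the alt-read probability);
* the matched blood carries germline heterozygous variants at AF ≈ 0.5 and
  sequencing error only at somatic loci;
* relapse biopsies, when enabled, descend from exactly one primary lesion's
  dominant subclone and add further private mutations under the same
  substitution spectrum (no chemotherapy-specific C>T enrichment unless
  configured).

An unrelated tumor cell line profile (independent mutation set, near-clonal
AFs) is generated per cohort to serve as the phylogeny outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from skbio import TreeNode

from .variant_io import (
    GenePanel,
    Locus,
    SampleMeta,
    VariantCall,
    write_gene_panel,
    write_newick,
    write_sample_sheet,
    write_variant_table,
)

__all__ = [
    "SimulationConfig",
    "ClonalTruth",
    "default_panel",
    "simulate_patient",
    "simulate_cohort",
    "reference_cohort_layout",
    "truth_compare",
    "relapse_attachment_ok",
    "site_separation_ok",
]

# Effect-class proportions follow the cohort-wide split observed in deep
# targeted EOC panels (non-synonymous : synonymous : indel : VUS
# = 416 : 106 : 45 : 564).
DEFAULT_EFFECT_PROBS = {
    "non_synonymous": 416 / 1131,
    "synonymous": 106 / 1131,
    "indel": 45 / 1131,
    "vus": 564 / 1131,
}
# C>T-dominant spectrum typical of ageing/APOBEC-exposed carcinomas
DEFAULT_SPECTRUM_PROBS = {
    "C>A": 0.08, "C>G": 0.08, "C>T": 0.40, "T>A": 0.08, "T>C": 0.24, "T>G": 0.12,
}

_SITE_CODES = {
    "ovary": "OV", "omentum": "OM", "peritoneum": "PE",
    "metastasis": "ME", "other": "OT",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CALLERS = frozenset({"mutect", "varscan"})


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    Defaults emulate a 65-gene amplicon panel sequenced to a mean depth of
    2500x on multi-biopsy EOC patients: two ovarian and two synchronous
    lesions per patient plus one relapse descending from one primary
    subclone, tumor purity 0.7, per-base error 1e-3.
    """

    n_patients: int = 2
    lesion_sites: tuple[str, ...] = ("ovary", "ovary", "omentum", "peritoneum")
    relapse: str = "from_one_primary_subclone"  # or "none"
    n_relapse: int = 1
    n_founder_mut: int = 12
    n_private_mut_mean: float = 15.0
    n_relapse_mut_mean: float | None = None  # defaults to n_private_mut_mean
    n_extra_subclones: int = 0  # unsampled dead-end subclones
    purity: float = 0.7
    mean_depth: int = 2500
    depth_dispersion: float = 50.0  # negative-binomial size parameter
    seq_error_rate: float = 1e-3
    n_germline_het: int = 30
    n_error_loci: int = 20
    n_control_mut: int = 40
    effect_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROBS)
    )
    spectrum_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_PROBS)
    )
    post_chemo_ct_multiplier: float = 1.0  # >1 enriches C>T on relapse edges

    def __post_init__(self) -> None:
        if not self.lesion_sites:
            raise ValueError("config must specify at least one lesion")
        if "ovary" not in self.lesion_sites:
            raise ValueError("each patient needs at least one ovary lesion")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if not (0.0 <= self.seq_error_rate <= 0.01):
            raise ValueError("seq_error_rate must be in [0, 0.01]")
        for name in ("n_patients", "n_founder_mut", "n_germline_het", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.relapse not in ("none", "from_one_primary_subclone"):
            raise ValueError(f"unknown relapse mode {self.relapse!r}")


# ---------------------------------------------------------------------------
# panel

_PANEL_GENES: dict[str, tuple[str, int]] = {
    # gene -> (pathway, coding length in bp); 65 genes
    "ATM": ("HR", 9171), "ATR": ("HR", 7935), "BRCA1": ("HR", 5592),
    "BRCA2": ("HR", 10257), "C11orf30": ("HR", 3942), "PALB2": ("HR", 3561),
    "RAD51": ("HR", 1020), "RAD51C": ("HR", 1131), "RAD51D": ("HR", 987),
    "CHEK1": ("HR", 1431), "CHEK2": ("HR", 1632), "FANCA": ("HR", 4368),
    "FANCD2": ("HR", 4416),
    "MLH1": ("MMR", 2271), "MSH2": ("MMR", 2805), "MSH6": ("MMR", 4083),
    "PMS2": ("MMR", 2589),
    "EGFR": ("RTK", 3633), "ERBB2": ("RTK", 3768), "ERBB3": ("RTK", 4026),
    "FGFR1": ("RTK", 2469), "FGFR2": ("RTK", 2466), "FGFR3": ("RTK", 2421),
    "MET": ("RTK", 4173), "KIT": ("RTK", 2931), "PDGFRA": ("RTK", 3270),
    "ALK": ("RTK", 4863), "IGF1R": ("RTK", 4104),
    "PIK3CA": ("PI3K_AKT_MTOR", 3207), "PIK3R1": ("PI3K_AKT_MTOR", 2175),
    "AKT1": ("PI3K_AKT_MTOR", 1443), "AKT2": ("PI3K_AKT_MTOR", 1446),
    "PTEN": ("PI3K_AKT_MTOR", 1212), "MTOR": ("PI3K_AKT_MTOR", 7650),
    "TSC1": ("PI3K_AKT_MTOR", 3495), "TSC2": ("PI3K_AKT_MTOR", 5424),
    "STK11": ("PI3K_AKT_MTOR", 1302),
    "KRAS": ("RAS_MAPK", 570), "NRAS": ("RAS_MAPK", 570),
    "BRAF": ("RAS_MAPK", 2301), "NF1": ("RAS_MAPK", 8520),
    "TP53": ("CELL_CYCLE", 1182), "RB1": ("CELL_CYCLE", 2787),
    "CCNE1": ("CELL_CYCLE", 1233), "CDK4": ("CELL_CYCLE", 912),
    "CDK6": ("CELL_CYCLE", 981), "CDKN2A": ("CELL_CYCLE", 471),
    "MDM2": ("CELL_CYCLE", 1476),
    "APC": ("WNT", 8532), "CTNNB1": ("WNT", 2346), "CDH1": ("WNT", 2649),
    "FN1": ("ADHESION_EMT", 7110), "VIM": ("ADHESION_EMT", 1401),
    "ZEB1": ("ADHESION_EMT", 3345), "ID4": ("ADHESION_EMT", 486),
    "VCAM1": ("ADHESION_EMT", 2220), "COL3A1": ("ADHESION_EMT", 4401),
    "TGFB3": ("TGFB", 1239), "SMAD4": ("TGFB", 1659),
    "ARID1A": ("CHROMATIN", 6858), "DICER1": ("CHROMATIN", 5769),
    "WT1": ("CHROMATIN", 1350),
    "ESR1": ("HORMONE", 1788), "PGR": ("HORMONE", 2802),
    "TOP2A": ("TOPOISOMERASE", 4596),
}


def default_panel() -> GenePanel:
    """The simulator's synthetic 65-gene panel (one interval per gene)."""
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    pathway_of: dict[str, str] = {}
    for i, (gene, (pathway, length)) in enumerate(sorted(_PANEL_GENES.items())):
        chrom = f"chr{i % 22 + 1}"
        start = 1_000_000 * (i // 22 + 1) + 10_000 * (i % 22)
        intervals[gene] = [(chrom, start, start + length)]
        pathway_of[gene] = pathway
    return GenePanel(intervals, pathway_of)


# ---------------------------------------------------------------------------
# truth

@dataclass
class ClonalTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    clone_tree: TreeNode  # clone names on nodes; root is the founder
    mutation_clone: dict[Locus, str]  # locus -> clone whose edge carries it
    clone_path: dict[str, tuple[str, ...]]  # clone -> clones root..clone
    biopsy_dominant: dict[str, str]  # sample_id -> dominant clone
    biopsy_composition: dict[str, dict[str, float]]
    mutation_info: dict[Locus, tuple[str, str]]  # locus -> (gene, effect)
    germline_loci: frozenset[Locus]
    error_loci: frozenset[Locus]

    @property
    def trunk_loci(self) -> set[Locus]:
        root = self.clone_tree.name
        return {l for l, c in self.mutation_clone.items() if c == root}

    def ccf(self, sample_id: str, locus: Locus) -> float:
        """True cancer-cell fraction of a mutation in a biopsy."""
        clone = self.mutation_clone.get(locus)
        if clone is None:
            return 0.0
        return sum(
            frac
            for dom, frac in self.biopsy_composition[sample_id].items()
            if clone in self.clone_path[dom]
        )

    def somatic_loci_of(self, sample_id: str) -> set[Locus]:
        return {l for l in self.mutation_clone if self.ccf(sample_id, l) > 0}

    @property
    def sampled_loci(self) -> set[Locus]:
        out: set[Locus] = set()
        for s in self.biopsy_dominant:
            out |= self.somatic_loci_of(s)
        return out

    @property
    def trunk_fraction(self) -> float:
        """Trunk mutations as a fraction of all mutations in sampled biopsies."""
        sampled = self.sampled_loci
        return len(self.trunk_loci & sampled) / len(sampled)

    def biopsy_lineage_tree(self) -> TreeNode:
        """The clone tree restricted to sampled biopsies, tips relabeled with
        sample ids (the topology a perfect reconstruction should recover)."""
        tree = self.clone_tree.copy()
        clone_to_sample: dict[str, list[str]] = {}
        for sample, clone in self.biopsy_dominant.items():
            clone_to_sample.setdefault(clone, []).append(sample)
        keep_names = []
        for clone, samples in clone_to_sample.items():
            node = tree.find(clone)
            for sample in sorted(samples):
                node.append(TreeNode(name=sample, length=0.0))
                keep_names.append(sample)
        sheared = tree.shear(keep_names)
        sheared.prune()
        return sheared


# ---------------------------------------------------------------------------
# generation helpers

def _draw_locus(
    panel: GenePanel,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    gene_probs: np.ndarray,
    genes: list[str],
    effect: str,
    spectrum_probs: Mapping[str, float],
) -> tuple[Locus, str]:
    classes = list(spectrum_probs)
    class_p = np.array([spectrum_probs[c] for c in classes])
    class_p = class_p / class_p.sum()
    while True:
        gene = genes[rng.choice(len(genes), p=gene_probs)]
        chrom, start, end = panel.intervals[gene][0]
        pos = int(rng.integers(start + 1, end))  # 1-based, inside interval
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        if effect == "indel":
            base = "ACGT"[rng.integers(4)]
            other = "ACGT"[rng.integers(4)]
            if rng.random() < 0.5:
                ref, alt = base, base + other  # 1 bp insertion
            else:
                ref, alt = base + other, base  # 1 bp deletion
        else:
            sub = classes[rng.choice(len(classes), p=class_p)]
            ref, alt = sub[0], sub[2]
            if rng.random() < 0.5:  # purine strand
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        return Locus(chrom, pos, ref, alt), gene


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    # negative binomial with mean `mean` and size parameter `dispersion`
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _sample_name(pid: str, site: str, site_counts: dict[str, int], n_same_site: int) -> str:
    code = _SITE_CODES[site]
    k = site_counts.get(site, 0)
    site_counts[site] = k + 1
    if site == "ovary" and n_same_site > 1:
        return f"{pid}-{'L' if k == 0 else 'R'}-{code}" if n_same_site == 2 else f"{pid}-{code}{k + 1}"
    return f"{pid}-{code}" if k == 0 else f"{pid}-{code}{k + 1}"


# ---------------------------------------------------------------------------
# patient and cohort simulation

def simulate_patient(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "P1",
    panel: GenePanel | None = None,
    relapse_stages: Sequence[str] | None = None,
    used_positions: set[tuple[str, int]] | None = None,
) -> tuple[dict[str, list[VariantCall]], list[SampleMeta], ClonalTruth]:
    """Simulate one patient: variant tables per biopsy and blood, plus truth.

    ``used_positions`` (shared across a cohort) keeps loci unique so one
    genomic variant never carries two different simulated effect classes.
    """
    if panel is None:
        panel = default_panel()
    genes = panel.genes
    lengths = np.array([panel.coding_length(g) for g in genes], dtype=float)
    gene_probs = lengths / lengths.sum()
    used: set[tuple[str, int]] = used_positions if used_positions is not None else set()

    effect_names = list(cfg.effect_probs)
    effect_p = np.array([cfg.effect_probs[e] for e in effect_names])
    effect_p = effect_p / effect_p.sum()

    relapse_spectrum = dict(cfg.spectrum_probs)
    if cfg.post_chemo_ct_multiplier != 1.0:
        relapse_spectrum["C>T"] *= cfg.post_chemo_ct_multiplier

    def draw_mutations(n: int, spectrum: Mapping[str, float]) -> list[tuple[Locus, str, str]]:
        out = []
        for _ in range(n):
            effect = effect_names[rng.choice(len(effect_names), p=effect_p)]
            locus, gene = _draw_locus(panel, rng, used, gene_probs, genes, effect, spectrum)
            out.append((locus, gene, effect))
        return out

    # --- subclone tree: founder -> two lineage stems -> one clone per lesion
    mutation_clone: dict[Locus, str] = {}
    mutation_info: dict[Locus, tuple[str, str]] = {}

    def place(clone: str, n: int, spectrum=None) -> None:
        for locus, gene, effect in draw_mutations(n, spectrum or cfg.spectrum_probs):
            mutation_clone[locus] = clone
            mutation_info[locus] = (gene, effect)

    founder = "founder"
    stems = {"ovary": "stem_ovary", "synchronous": "stem_sync"}
    place(founder, cfg.n_founder_mut)
    for stem in stems.values():
        place(stem, int(rng.poisson(cfg.n_private_mut_mean)))

    n_ovary = sum(1 for s in cfg.lesion_sites if s == "ovary")
    site_counts: dict[str, int] = {}
    samples: list[SampleMeta] = []
    biopsy_dominant: dict[str, str] = {}
    clone_children: dict[str, list[str]] = {founder: list(stems.values())}
    for site in cfg.lesion_sites:
        name = _sample_name(patient_id, site, site_counts, n_ovary if site == "ovary" else 0)
        stem = stems["ovary" if site == "ovary" else "synchronous"]
        clone = f"clone_{name}"
        clone_children.setdefault(stem, []).append(clone)
        place(clone, int(rng.poisson(cfg.n_private_mut_mean)))
        biopsy_dominant[name] = clone
        samples.append(
            SampleMeta(name, patient_id, "tumor", site=site, stage="primary")
        )

    # unsampled dead-end subclones
    for i in range(cfg.n_extra_subclones):
        host = list(stems.values())[int(rng.integers(2))]
        clone = f"clone_unsampled_{i + 1}"
        clone_children.setdefault(host, []).append(clone)
        place(clone, int(rng.poisson(cfg.n_private_mut_mean)))

    # relapse biopsies descend from one primary lesion's dominant subclone
    if cfg.relapse == "from_one_primary_subclone" and cfg.n_relapse > 0:
        sync_samples = [m for m in samples if m.site != "ovary"]
        parent_meta = sync_samples[0] if sync_samples else samples[0]
        parent_clone = biopsy_dominant[parent_meta.sample_id]
        relapse_mean = (
            cfg.n_relapse_mut_mean
            if cfg.n_relapse_mut_mean is not None
            else cfg.n_private_mut_mean
        )
        stages = list(relapse_stages or [])
        for i in range(cfg.n_relapse):
            stage = stages[i] if i < len(stages) else "second_surgery"
            suffix = "3ME" if stage == "third_surgery" else "2ME"
            code = _SITE_CODES[parent_meta.site]
            name = f"{patient_id}-{code}-{suffix}" if i == 0 else \
                f"{patient_id}-{code}{i + 1}-{suffix}"
            clone = f"clone_{name}"
            clone_children.setdefault(parent_clone, []).append(clone)
            place(clone, int(rng.poisson(relapse_mean)), relapse_spectrum)
            biopsy_dominant[name] = clone
            samples.append(
                SampleMeta(name, patient_id, "tumor",
                           site=parent_meta.site, stage=stage)
            )

    # assemble the clone tree and root->clone paths
    def build(clone: str) -> TreeNode:
        node = TreeNode(name=clone, length=1.0)
        for child in clone_children.get(clone, []):
            node.append(build(child))
        return node

    clone_tree = build(founder)
    clone_tree.length = None
    clone_path: dict[str, tuple[str, ...]] = {}

    def walk(node: TreeNode, path: tuple[str, ...]) -> None:
        path = path + (node.name,)
        clone_path[node.name] = path
        for child in node.children:
            walk(child, path)

    walk(clone_tree, ())

    biopsy_composition = {s: {c: 1.0} for s, c in biopsy_dominant.items()}

    # germline heterozygous variants (present in blood and every tumor sample)
    germline: set[Locus] = set()
    for locus, gene, effect in draw_mutations(cfg.n_germline_het, cfg.spectrum_probs):
        germline.add(locus)
    # error-only candidate positions
    error_loci: set[Locus] = set()
    for locus, gene, effect in draw_mutations(cfg.n_error_loci, cfg.spectrum_probs):
        error_loci.add(locus)

    blood_name = f"{patient_id}-BL"
    samples.append(SampleMeta(blood_name, patient_id, "blood"))

    truth = ClonalTruth(
        patient_id=patient_id,
        clone_tree=clone_tree,
        mutation_clone=mutation_clone,
        clone_path=clone_path,
        biopsy_dominant=biopsy_dominant,
        biopsy_composition=biopsy_composition,
        mutation_info=mutation_info,
        germline_loci=frozenset(germline),
        error_loci=frozenset(error_loci),
    )

    # --- sequencing
    err3 = cfg.seq_error_rate / 3.0
    calls: dict[str, list[VariantCall]] = {}
    somatic_loci = sorted(mutation_clone)
    germline_sorted = sorted(germline)
    error_sorted = sorted(error_loci)
    for meta in samples:
        sample_calls: list[VariantCall] = []
        is_blood = meta.role == "blood"
        for locus in somatic_loci + germline_sorted + error_sorted:
            if locus in germline:
                p_alt = 0.5
                gene, effect = None, "unclassified"
            elif is_blood:
                p_alt = err3
                gene, effect = mutation_info.get(locus, (None, "unclassified"))
            else:
                ccf = truth.ccf(meta.sample_id, locus)
                p_alt = cfg.purity * ccf * 0.5 + err3
                gene, effect = mutation_info.get(locus, (None, "unclassified"))
            depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion))
            alt = int(rng.binomial(depth, min(p_alt, 1.0))) if depth > 0 else 0
            if alt == 0 and not is_blood:
                continue  # a caller reports nothing without alt reads
            if locus in error_loci:
                gene, effect = None, "unclassified"
            if gene is None:
                gene = panel.gene_at(locus)
            sample_calls.append(
                VariantCall.from_counts(
                    meta.sample_id, locus, depth, alt,
                    callers=_CALLERS, gene=gene,
                    effect=effect if not is_blood else "unclassified",
                )
            )
        calls[meta.sample_id] = sample_calls
    return calls, samples, truth


def simulate_control(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    panel: GenePanel | None = None,
    sample_id: str = "OVCAR-8",
    used_positions: set[tuple[str, int]] | None = None,
) -> tuple[list[VariantCall], SampleMeta]:
    """An unrelated tumor cell-line profile used as the phylogeny outgroup.

    Synthetic stand-in for an unrelated control line: its mutation set is
    drawn independently of every patient, near-clonal (AF ~ 0.5).
    """
    if panel is None:
        panel = default_panel()
    genes = panel.genes
    lengths = np.array([panel.coding_length(g) for g in genes], dtype=float)
    gene_probs = lengths / lengths.sum()
    used: set[tuple[str, int]] = used_positions if used_positions is not None else set()
    calls: list[VariantCall] = []
    for _ in range(cfg.n_control_mut):
        locus, gene = _draw_locus(
            panel, rng, used, gene_probs, genes, "snv", cfg.spectrum_probs
        )
        depth = int(_nb_depth(rng, cfg.mean_depth, cfg.depth_dispersion))
        alt = int(rng.binomial(depth, 0.5)) if depth > 0 else 0
        calls.append(
            VariantCall.from_counts(sample_id, locus, depth, alt,
                                    callers=_CALLERS, gene=gene, effect="vus")
        )
    meta = SampleMeta(sample_id, sample_id, "control")
    return calls, meta


def reference_cohort_layout(n_patients: int = 19) -> list[dict]:
    """A cohort layout matching the reference study's structure: for 19
    patients, 21 ovary + 24 synchronous primary biopsies and 26 follow-up
    biopsies (71 tumor biopsies, 19 bloods), including one patient with
    bilateral ovarian sampling and third-surgery follow-up."""
    layouts: list[dict] = []
    for i in range(n_patients):
        sites = ["ovary"]
        if i in (0, 1):
            sites.append("ovary")  # bilateral sampling
        sites.append("omentum")
        if i in (2, 3, 4, 5, 6):
            sites.append("peritoneum")
        n_rel, stages = 1, ["second_surgery"]
        if i == 0:
            n_rel, stages = 3, ["second_surgery", "second_surgery", "third_surgery"]
        elif i in (7, 8, 9, 10, 11):
            n_rel, stages = 2, ["second_surgery", "second_surgery"]
        layouts.append(
            {"lesion_sites": tuple(sites), "n_relapse": n_rel,
             "relapse_stages": stages}
        )
    return layouts


def simulate_cohort(
    cfg: SimulationConfig,
    seed: int,
    out_dir: str | Path | None = None,
    layouts: Sequence[dict] | None = None,
):
    """Simulate a cohort; optionally write the file bundle.

    Returns ``(calls_by_sample, metas, truths, panel)``. With ``out_dir`` set,
    writes ``variants.tsv``, ``samples.tsv``, ``panel.bed``, ``pathways.tsv``,
    per-patient truth trees (Newick) and a YAML truth manifest; identical
    config + seed produce byte-identical files.
    """
    rng = np.random.default_rng(seed)
    panel = default_panel()
    used_positions: set[tuple[str, int]] = set()
    calls_by_sample: dict[str, list[VariantCall]] = {}
    metas: list[SampleMeta] = []
    truths: dict[str, ClonalTruth] = {}
    for i in range(cfg.n_patients):
        pid = str(20001 + i)
        pcfg = cfg
        relapse_stages = None
        if layouts is not None:
            lay = layouts[i % len(layouts)]
            pcfg = replace(cfg, lesion_sites=lay["lesion_sites"],
                           n_relapse=lay["n_relapse"])
            relapse_stages = lay.get("relapse_stages")
        pcalls, pmetas, truth = simulate_patient(
            pcfg, rng, pid, panel, relapse_stages=relapse_stages,
            used_positions=used_positions,
        )
        calls_by_sample.update(pcalls)
        metas.extend(pmetas)
        truths[pid] = truth
    control_calls, control_meta = simulate_control(
        cfg, rng, panel, used_positions=used_positions
    )
    calls_by_sample[control_meta.sample_id] = control_calls
    metas.append(control_meta)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        variants_path = out / "variants.tsv"
        if variants_path.exists():
            raise FileExistsError(f"output collision: {variants_path} exists")
        all_calls = [c for s in sorted(calls_by_sample) for c in calls_by_sample[s]]
        write_variant_table(all_calls, variants_path)
        write_sample_sheet(metas, out / "samples.tsv")
        write_gene_panel(panel, out / "panel.bed", out / "pathways.tsv")
        trees_dir = out / "truth_trees"
        trees_dir.mkdir(exist_ok=True)
        manifest: dict = {"seed": seed, "patients": {}}
        for pid, truth in truths.items():
            write_newick(truth.clone_tree, trees_dir / f"{pid}.nwk")
            manifest["patients"][pid] = {
                "n_mutations": len(truth.mutation_clone),
                "n_trunk": len(truth.trunk_loci),
                "trunk_fraction": float(truth.trunk_fraction),
                "biopsy_dominant": dict(sorted(truth.biopsy_dominant.items())),
            }
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return calls_by_sample, metas, truths, panel


# ---------------------------------------------------------------------------
# recovery instrumentation

def truth_compare(
    truth: ClonalTruth,
    passing_by_sample: Mapping[str, Sequence[VariantCall]],
    inferred_tree: TreeNode | None = None,
    outgroup_id: str | None = None,
    min_expected_af: float = 0.05,
    purity: float | None = None,
) -> dict:
    """Recovery report of the pipeline against simulator ground truth.

    Reports somatic-call sensitivity (over true mutations whose expected AF is
    at least ``min_expected_af``) and specificity (over germline and
    error-only loci), the unrooted Robinson-Foulds distance between the
    inferred patient tree and the true lineage tree restricted to sampled
    biopsies, and the absolute error of the concordant percentage against the
    true trunk fraction.
    """
    sample_ids = set(truth.biopsy_dominant)
    missing = sample_ids - set(passing_by_sample)
    if missing:
        raise ValueError(f"pipeline output lacks samples {sorted(missing)}")
    purity = purity if purity is not None else 1.0

    called: dict[str, set[Locus]] = {
        s: {c.locus for c in passing_by_sample[s]} for s in sample_ids
    }
    tp = fn = 0
    for s in sorted(sample_ids):
        for locus in truth.somatic_loci_of(s):
            if purity * truth.ccf(s, locus) * 0.5 < min_expected_af:
                continue
            if locus in called[s]:
                tp += 1
            else:
                fn += 1
    negatives = truth.germline_loci | truth.error_loci
    fp = tn = 0
    for s in sorted(sample_ids):
        for locus in negatives:
            if locus in called[s]:
                fp += 1
            else:
                tn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")

    # concordant percentage of an (ovary, synchronous) primary pair
    from .hetstats import leaf_pair_similarity

    universe: set[Locus] = set()
    for s in sample_ids:
        universe |= called[s]
    def _primary_of(stem: str) -> list[str]:
        return sorted(
            s for s, clone in truth.biopsy_dominant.items()
            if stem in truth.clone_path[clone] and len(truth.clone_path[clone]) == 3
        )

    ovary = _primary_of("stem_ovary")
    sync = _primary_of("stem_sync")
    concordant_error = float("nan")
    if ovary and sync and universe:
        triple = leaf_pair_similarity(ovary[0], sync[0], called, universe)
        concordant_error = abs(triple.concordant_pct - 100.0 * truth.trunk_fraction)

    rf = float("nan")
    if inferred_tree is not None:
        inferred = inferred_tree.copy()
        if outgroup_id is not None:
            inferred = inferred.shear(
                [t.name for t in inferred.tips() if t.name != outgroup_id]
            )
            inferred.prune()
        true_tree = truth.biopsy_lineage_tree()
        rf = float(inferred.compare_rfd(true_tree, rooted=False))

    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "concordant_pct_error": concordant_error,
        "rf_distance": rf,
        "n_true_positive": tp,
        "n_false_negative": fn,
        "n_false_positive": fp,
    }


def relapse_attachment_ok(
    truth: ClonalTruth, tree: TreeNode, outgroup_id: str | None = None
) -> bool:
    """Does every relapse leaf attach inside the clade of its parent lesion?

    For each relapse biopsy, walk up from its leaf to the smallest clade that
    contains at least one primary biopsy; the check passes when that clade
    contains the lesion whose dominant subclone the relapse descends from.
    """
    primaries = {
        s for s, clone in truth.biopsy_dominant.items()
        if len(truth.clone_path[clone]) == 3
    }
    relapses = set(truth.biopsy_dominant) - primaries
    if not relapses:
        raise ValueError("truth contains no relapse biopsies")
    for r in sorted(relapses):
        clone_path = truth.clone_path[truth.biopsy_dominant[r]]
        parent_clone = clone_path[-2]  # the primary subclone it descends from
        parent_lesions = {
            s for s, c in truth.biopsy_dominant.items() if c == parent_clone
        }
        node = tree.find(r)
        while node.parent is not None:
            node = node.parent
            clade = {t.name for t in node.tips()} - {outgroup_id}
            clade_primaries = clade & primaries
            if clade_primaries:
                if not clade_primaries & parent_lesions:
                    return False
                break
    return True


def site_separation_ok(
    metas: Sequence[SampleMeta], flat_clusters: Mapping[str, int]
) -> bool:
    """Does a k=2 sample cut split ovary from synchronous primary biopsies?"""
    ovary = {m.sample_id for m in metas
             if m.is_primary_tumor and m.site == "ovary"}
    sync = {m.sample_id for m in metas
            if m.is_primary_tumor and m.site != "ovary"}
    ovary &= set(flat_clusters)
    sync &= set(flat_clusters)
    if not ovary or not sync:
        raise ValueError("need both ovary and synchronous samples in the clustering")
    ovary_labels = {flat_clusters[s] for s in ovary}
    sync_labels = {flat_clusters[s] for s in sync}
    return len(ovary_labels) == 1 and len(sync_labels) == 1 and ovary_labels != sync_labels
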