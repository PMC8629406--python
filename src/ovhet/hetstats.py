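"""Heterogeneity statistics: mutational burden, per-gene/per-pathway counts,
concordance heatmap matrices, and leaf-pair similarity.

Leaf-pair similarity partitions a patient's somatic-locus universe (every
locus passing filters in at least one of the patient's samples) into three
bins for a pair of biopsies: *concordant* (called in both), *private* (called
in exactly one) and *wt* (called in neither — the locus is somatic elsewhere
in the patient but wild type in both members of the pair). The three
percentages sum to 100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .variant_io import GenePanel, Locus, SampleMeta, VariantCall

__all__ = [
    "mutational_burden",
    "per_gene_counts",
    "per_pathway_counts",
    "concordance_heatmap_matrix",
    "SimilarityTriple",
    "leaf_pair_similarity",
]

_EFFECTS = ("non_synonymous", "synonymous", "indel", "vus")


def mutational_burden(
    calls: Sequence[VariantCall], meta: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Per-sample mutation counts by effect class (tumor samples only).

    Returns one row per tumor sample (including samples with zero passing
    calls) with the four effect-class counts and their total.
    """
    tumor_ids = [m.sample_id for m in meta if m.role == "tumor"]
    counts = pd.DataFrame(0, index=tumor_ids, columns=list(_EFFECTS))
    for c in calls:
        if c.sample_id in counts.index and c.effect in _EFFECTS:
            counts.loc[c.sample_id, c.effect] += 1
    counts["total"] = counts.sum(axis=1)
    counts.index.name = "sample_id"
    return counts


def _compartment_of(m: SampleMeta) -> str:
    if m.is_relapse:
        return "metachronous"
    return "ovary" if m.site == "ovary" else "synchronous"


def per_gene_counts(
    calls: Sequence[VariantCall],
    panel: GenePanel,
    meta: Sequence[SampleMeta],
    group_by: str = "compartment",
) -> pd.DataFrame:
    """Passing-variant counts per panel gene per group.

    ``group_by='compartment'`` groups tumor samples into ovary / synchronous /
    metachronous; ``group_by='sample'`` keeps samples separate. Calls falling
    outside every panel gene are reported under ``off_target``.
    """
    if group_by not in ("compartment", "sample"):
        raise ValueError(f"unknown group_by {group_by!r}")
    midx = {m.sample_id: m for m in meta}
    if group_by == "compartment":
        groups = ["ovary", "synchronous", "metachronous"]
    else:
        groups = sorted(m.sample_id for m in meta if m.role == "tumor")
    rows = panel.genes + ["off_target"]
    out = pd.DataFrame(0, index=rows, columns=groups)
    for c in calls:
        m = midx.get(c.sample_id)
        if m is None or m.role != "tumor":
            continue
        group = _compartment_of(m) if group_by == "compartment" else m.sample_id
        gene = c.gene if c.gene in panel.intervals else panel.gene_at(c.locus)
        out.loc[gene if gene is not None else "off_target", group] += 1
    out.index.name = "gene"
    return out


def per_pathway_counts(
    gene_counts: pd.DataFrame, panel: GenePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-gene counts to pathways and compare compartments.

    Returns ``(pathway_counts, tests)``. Pathway counts are sums over member
    genes (off_target excluded). When the count matrix has ovary and
    synchronous columns, each pathway's share of mutations is compared between
    the two compartments with a two-sided two-proportion z-test; ``tests``
    has one row per pathway with the z statistic and p-value.
    """
    for gene in gene_counts.index:
        if gene != "off_target" and gene not in panel.pathway_of:
            raise ValueError(f"gene {gene} has no pathway label")
    body = gene_counts.drop(index="off_target", errors="ignore")
    pathways = pd.Series({g: panel.pathway_of[g] for g in body.index}, name="pathway")
    pw = body.groupby(pathways).sum().sort_index()
    pw.index.name = "pathway"

    tests = pd.DataFrame(columns=["ovary", "synchronous", "zstat", "pvalue"])
    if {"ovary", "synchronous"} <= set(pw.columns):
        n_ov, n_sy = int(pw["ovary"].sum()), int(pw["synchronous"].sum())
        recs = []
        for pathway, row in pw.iterrows():
            k_ov, k_sy = int(row["ovary"]), int(row["synchronous"])
            if n_ov == 0 or n_sy == 0 or (k_ov == 0 and k_sy == 0):
                z, p = np.nan, np.nan
            else:
                z, p = proportions_ztest([k_ov, k_sy], [n_ov, n_sy])
            recs.append({"pathway": pathway, "ovary": k_ov, "synchronous": k_sy,
                         "zstat": z, "pvalue": p})
        tests = pd.DataFrame(recs).set_index("pathway")
    return pw, tests


def concordance_heatmap_matrix(
    patient_labels: Mapping[str, Mapping[Locus, str]],
    panel: GenePanel,
) -> pd.DataFrame:
    """Patient × gene matrix of concordant-mutation counts.

    ``patient_labels`` maps patient id to that patient's locus→label map from
    :func:`ovhet.classify.label_concordant_patient`. Cells are 0 where a
    patient has no concordant locus in a gene (the heatmap's gray).
    """
    patients = sorted(patient_labels)
    out = pd.DataFrame(0, index=patients, columns=panel.genes + ["off_target"])
    for pid, labels in patient_labels.items():
        for locus, label in labels.items():
            if label != "concordant":
                continue
            gene = panel.gene_at(locus)
            out.loc[pid, gene if gene is not None else "off_target"] += 1
    out.index.name = "patient_id"
    return out


@dataclass(frozen=True)
class SimilarityTriple:
    """Pairwise leaf similarity: percent concordant / private / wild type."""

    sample_a: str
    sample_b: str
    concordant_pct: float
    private_pct: float
    wt_pct: float

    def __post_init__(self) -> None:
        total = self.concordant_pct + self.private_pct + self.wt_pct
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"similarity percentages sum to {total}, not 100")

    def as_row(self) -> dict:
        # Column names follow the field's reporting convention
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "Concordant mutations": f"{self.concordant_pct:.2f}%",
            "Private mutations": f"{self.private_pct:.2f}%",
            "Wt": f"{self.wt_pct:.2f}%",
        }


def leaf_pair_similarity(
    sample_a: str,
    sample_b: str,
    calls_by_sample: Mapping[str, Iterable[Locus] | set[Locus]],
    patient_universe: set[Locus],
) -> SimilarityTriple:
    """Partition a patient's locus universe for one biopsy pair.

    ``patient_universe`` must contain every locus somatic in >= 1 sample of
    the patient owning both biopsies; percentages are over its size.
    """
    if not patient_universe:
        raise ValueError("empty locus universe: similarity percentages undefined")
    loci_a = set(calls_by_sample.get(sample_a, ())) & patient_universe
    loci_b = set(calls_by_sample.get(sample_b, ())) & patient_universe
    n = len(patient_universe)
    n_conc = len(loci_a & loci_b)
    n_priv = len(loci_a ^ loci_b)
    conc = round(100.0 * n_conc / n, 2)
    priv = round(100.0 * n_priv / n, 2)
    # wt takes the rounding residual so the triple sums to exactly 100
    wt = round(100.0 - conc - priv, 2)
    return SimilarityTriple(sample_a, sample_b, conc, priv, wt)
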