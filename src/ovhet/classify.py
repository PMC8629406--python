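"""Variant effect classes and sharing partitions.

Effect classes follow the four-way scheme used in targeted-panel studies of
ovarian cancer: non-synonymous, synonymous, indel (<50 bp), and VUS (variant
of unknown significance — here, a substitution with no usable codon
annotation).

Sharing partitions come in two scopes:

* cohort scope — a locus is *shared* when it is somatic in at least one ovary
  sample and at least one synchronous (non-ovarian, primary-surgery) lesion
  anywhere in the cohort, not necessarily in the same patient;
* patient scope — a locus is *concordant* when it is somatic in the patient's
  ovary and in at least one of that same patient's synchronous lesions;
  otherwise it is *private* to the sample carrying it. Loci recurring in two
  or more synchronous lesions without ovarian support get their own label,
  ``synchronous_recurrent``, rather than being forced into the binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .variant_io import Locus, SampleMeta, VariantCall

__all__ = [
    "classify_effect",
    "annotate_effects",
    "label_sharing_cohort",
    "label_concordant_patient",
    "CategoryTable",
    "category_table",
    "category_table_from_counts",
]

EFFECT_ORDER = ("non_synonymous", "synonymous", "indel", "vus")
COMPARTMENTS = ("ovary", "synchronous", "shared")


def classify_effect(locus: Locus, annotation: tuple[str, str] | None = None) -> str:
    """Effect class of a variant.

    ``annotation``, when present, is the (reference codon, alternate codon)
    pair for a substitution. Length-changing variants are indels; annotated
    substitutions are synonymous or non-synonymous by the standard genetic
    code; unannotated substitutions are VUS.
    """
    diff = abs(len(locus.ref) - len(locus.alt))
    if diff > 0:
        if diff >= 50:
            raise ValueError(
                f"length change {diff} >= 50 bp at {locus}: out of panel scope"
            )
        return "indel"
    if annotation is None:
        return "vus"
    ref_codon, alt_codon = annotation
    if str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate()):
        return "synonymous"
    return "non_synonymous"


def annotate_effects(
    calls: Iterable[VariantCall],
    annotations: Mapping[Locus, tuple[str, str]] | None = None,
) -> list[VariantCall]:
    """Fill in effect labels for calls that lack them.

    Calls already carrying an explicit effect (e.g. simulator output or a
    pre-annotated table) are kept as-is; the rest are classified from alleles
    and the optional codon-annotation map.
    """
    annotations = annotations or {}
    out = []
    for c in calls:
        if c.effect != "unclassified":
            out.append(c)
        else:
            effect = classify_effect(c.locus, annotations.get(c.locus))
            out.append(
                VariantCall(c.sample_id, c.locus, c.depth, c.alt_reads, c.af,
                            c.callers, effect, c.gene)
            )
    return out


def _meta_index(meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def label_sharing_cohort(
    calls: Sequence[VariantCall], meta: Sequence[SampleMeta]
) -> dict[Locus, str]:
    """Cohort-wide shared/not_shared labels over primary-surgery samples.

    A locus is shared when somatic in >= 1 ovary sample and >= 1 non-ovary
    primary (synchronous) sample, across the whole cohort.
    """
    midx = _meta_index(meta)
    in_ovary: set[Locus] = set()
    in_sync: set[Locus] = set()
    loci: set[Locus] = set()
    for c in calls:
        m = midx.get(c.sample_id)
        if m is None or not m.is_primary_tumor:
            continue
        loci.add(c.locus)
        if m.site == "ovary":
            in_ovary.add(c.locus)
        else:
            in_sync.add(c.locus)
    return {
        locus: ("shared" if locus in in_ovary and locus in in_sync else "not_shared")
        for locus in loci
    }


def label_concordant_patient(
    calls: Sequence[VariantCall], meta: Sequence[SampleMeta]
) -> dict[Locus, str]:
    """Per-patient concordant/private/synchronous_recurrent labels.

    Considers the patient's primary-surgery samples only (concordance is
    defined between the ovary and its synchronous lesions). Loci found in
    multiple ovary samples but no synchronous lesion are counted as private;
    they do not satisfy the concordance definition.
    """
    midx = _meta_index(meta)
    patients = {
        midx[c.sample_id].patient_id
        for c in calls
        if c.sample_id in midx and midx[c.sample_id].role == "tumor"
    }
    if len(patients) > 1:
        raise ValueError(f"calls span multiple patients: {sorted(patients)}")

    ovary_samples = {
        m.sample_id for m in meta if m.is_primary_tumor and m.site == "ovary"
    }
    sync_samples = {
        m.sample_id for m in meta if m.is_primary_tumor and m.site != "ovary"
    }
    if patients:
        pid = next(iter(patients))
        p_ovary = {s for s in ovary_samples if midx[s].patient_id == pid}
        p_sync = {s for s in sync_samples if midx[s].patient_id == pid}
        if not p_ovary:
            raise ValueError(f"patient {pid} has no ovary sample")
        if not p_sync:
            raise ValueError(f"patient {pid} has no synchronous primary sample")

    ovary_n: dict[Locus, int] = {}
    sync_n: dict[Locus, int] = {}
    for c in calls:
        if c.sample_id in ovary_samples:
            ovary_n[c.locus] = ovary_n.get(c.locus, 0) + 1
        elif c.sample_id in sync_samples:
            sync_n[c.locus] = sync_n.get(c.locus, 0) + 1

    labels: dict[Locus, str] = {}
    for locus in set(ovary_n) | set(sync_n):
        o, s = ovary_n.get(locus, 0), sync_n.get(locus, 0)
        if o >= 1 and s >= 1:
            labels[locus] = "concordant"
        elif s >= 2:
            labels[locus] = "synchronous_recurrent"
        else:
            labels[locus] = "private"
    return labels


@dataclass
class CategoryTable:
    """Compartment × effect counts with totals and headline fractions.

    Rows are mutually exclusive compartments: loci shared between the ovary
    and the synchronous compartment (cohort scope) are counted once in the
    shared row and excluded from the exclusive ovary/synchronous rows.
    """

    table: pd.DataFrame  # rows ovary/synchronous/shared/total, columns effects + total

    @property
    def grand_total(self) -> int:
        return int(self.table.loc["total", "total"])

    def compartment_total(self, compartment: str) -> int:
        return int(self.table.loc[compartment, "total"])

    @property
    def shared_fraction_pct(self) -> float:
        """Shared variants as a percentage of all variants, to one decimal."""
        return round(100.0 * self.compartment_total("shared") / self.grand_total, 1)

    @property
    def shared_vus_fraction_pct(self) -> float:
        """Shared VUS as a percentage of all VUS, to one decimal."""
        return round(
            100.0 * self.table.loc["shared", "vus"] / self.table.loc["total", "vus"], 1
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def category_table_from_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> CategoryTable:
    """Build the compartment × effect table from per-cell counts."""
    df = pd.DataFrame(
        [[int(counts.get(comp, {}).get(eff, 0)) for eff in EFFECT_ORDER]
         for comp in COMPARTMENTS],
        index=list(COMPARTMENTS),
        columns=list(EFFECT_ORDER),
    )
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return CategoryTable(df)


def category_table(
    calls: Sequence[VariantCall],
    meta: Sequence[SampleMeta],
    sharing: Mapping[Locus, str] | None = None,
) -> CategoryTable:
    """Count somatic variants by compartment (ovary-exclusive,
    synchronous-exclusive, shared) and effect class.

    Shared loci (cohort scope) count once in the shared row. Non-shared loci
    count once per patient per compartment: a locus in two ovary samples of
    one patient contributes one ovary count for that patient, but the same
    locus in another patient's ovary contributes again.
    """
    midx = _meta_index(meta)
    if sharing is None:
        sharing = label_sharing_cohort(calls, meta)

    effect_of: dict[Locus, str] = {}
    for c in calls:
        if c.effect == "unclassified":
            raise ValueError(f"call without effect label at {c.locus} ({c.sample_id})")
        prev = effect_of.setdefault(c.locus, c.effect)
        if prev != c.effect:
            raise ValueError(f"conflicting effect labels for {c.locus}: {prev}/{c.effect}")

    counts: dict[str, dict[str, int]] = {c: {} for c in COMPARTMENTS}
    shared_done: set[Locus] = set()
    per_patient: dict[tuple[str, str, Locus], None] = {}
    for c in calls:
        m = midx.get(c.sample_id)
        if m is None or not m.is_primary_tumor:
            continue
        locus = c.locus
        if sharing.get(locus) == "shared":
            if locus not in shared_done:
                shared_done.add(locus)
                eff = effect_of[locus]
                counts["shared"][eff] = counts["shared"].get(eff, 0) + 1
        else:
            comp = "ovary" if m.site == "ovary" else "synchronous"
            key = (m.patient_id, comp, locus)
            if key not in per_patient:
                per_patient[key] = None
                eff = effect_of[locus]
                counts[comp][eff] = counts[comp].get(eff, 0) + 1
    return category_table_from_counts(counts)
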