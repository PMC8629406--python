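"""Shared data model and readers/writers for variant tables, sample sheets,
gene panels, and phylogenetic trees.

The pipeline's internal tabular dialect is a tab-separated file with a header
row and columns ``sample_id, chrom, pos, ref, alt, depth, alt_reads`` plus
optional ``af, gene, effect, callers``. VCF input (v4.x, with per-sample
AD/DP-style counts) is converted to the same in-memory records, so the
simulator output and real caller output converge on one representation.

Coordinates: variant positions are 1-based as in VCF; panel intervals are
BED-style and stored 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "EFFECTS",
    "ROLES",
    "SITES",
    "STAGES",
    "HISTOTYPES",
    "GRADES",
    "PT_STATUSES",
    "Locus",
    "VariantCall",
    "SampleMeta",
    "GenePanel",
    "AFMatrix",
    "read_variant_table",
    "write_variant_table",
    "read_sample_sheet",
    "read_gene_panel",
    "read_newick",
    "write_newick",
]

EFFECTS = ("non_synonymous", "synonymous", "indel", "vus", "unclassified")
ROLES = ("tumor", "blood", "control")
SITES = ("ovary", "omentum", "peritoneum", "metastasis", "other")
STAGES = ("primary", "second_surgery", "third_surgery")
HISTOTYPES = ("serous", "endometrioid", "mucinous")
GRADES = ("high", "low")
PT_STATUSES = ("sensitive", "resistant", "unknown")

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class Locus:
    """A variant locus identified by (chrom, pos, ref, alt).

    Identity is allele-aware by default: two substitutions at the same
    genomic position are different loci. Use :meth:`site_key` for the looser
    position-only reading.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _BASES:
                raise ValueError(f"{name} allele {allele!r} is not a nonempty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantCall:
    """One somatic call of one sample: counts, allelic fraction, provenance."""

    sample_id: str
    locus: Locus
    depth: int
    alt_reads: int
    af: float
    callers: frozenset[str] = frozenset()
    effect: str = "unclassified"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("depth and alt_reads must be nonnegative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} > depth {self.depth} at {self.locus}"
            )
        if not (0.0 <= self.af <= 1.0) or math.isnan(self.af):
            raise ValueError(f"af {self.af} outside [0, 1] at {self.locus}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "indel" and not (
            self.locus.is_indel and abs(len(self.locus.ref) - len(self.locus.alt)) < 50
        ):
            raise ValueError(f"effect=indel inconsistent with alleles at {self.locus}")
        self.callers = frozenset(self.callers)

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        locus: Locus,
        depth: int,
        alt_reads: int,
        **kwargs,
    ) -> "VariantCall":
        af = alt_reads / depth if depth > 0 else 0.0
        return cls(sample_id, locus, depth, alt_reads, af, **kwargs)


@dataclass(frozen=True)
class SampleMeta:
    """Biopsy annotations: who the sample belongs to and where/when it was taken."""

    sample_id: str
    patient_id: str
    role: str
    site: str | None = None
    stage: str | None = None
    histotype: str | None = None
    grade: str | None = None
    pt_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.sample_id}")
        if self.role == "tumor":
            if self.site not in SITES:
                raise ValueError(f"unknown site {self.site!r} for sample {self.sample_id}")
            if self.stage not in STAGES:
                raise ValueError(f"unknown stage {self.stage!r} for sample {self.sample_id}")
        for name, value, allowed in (
            ("histotype", self.histotype, HISTOTYPES),
            ("grade", self.grade, GRADES),
        ):
            if value is not None and value not in allowed:
                raise ValueError(f"unknown {name} {value!r} for sample {self.sample_id}")
        if self.pt_status not in PT_STATUSES:
            raise ValueError(f"unknown pt_status {self.pt_status!r}")

    @property
    def is_primary_tumor(self) -> bool:
        return self.role == "tumor" and self.stage == "primary"

    @property
    def is_relapse(self) -> bool:
        return self.role == "tumor" and self.stage in ("second_surgery", "third_surgery")


class GenePanel:
    """A targeted gene panel: per-gene genomic intervals plus a gene→pathway map.

    Intervals are 0-based half-open. Intervals may not overlap (within or
    across genes), so every position maps to at most one panel gene.
    """

    def __init__(
        self,
        intervals: Mapping[str, Sequence[tuple[str, int, int]]],
        pathway_of: Mapping[str, str],
    ) -> None:
        self.intervals: dict[str, list[tuple[str, int, int]]] = {
            g: sorted((str(c), int(s), int(e)) for c, s, e in ivs)
            for g, ivs in intervals.items()
        }
        self.pathway_of = dict(pathway_of)
        for gene, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                if start >= end:
                    raise ValueError(f"empty interval {chrom}:{start}-{end} for gene {gene}")
            if gene not in self.pathway_of:
                raise ValueError(f"panel gene {gene} has no pathway label")
        self._check_no_overlap()
        # per-chromosome sorted interval index
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                self._by_chrom.setdefault(chrom, []).append((start, end, gene))
        for ivs in self._by_chrom.values():
            ivs.sort()

    def _check_no_overlap(self) -> None:
        flat: dict[str, list[tuple[int, int, str]]] = {}
        for gene, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                flat.setdefault(chrom, []).append((start, end, gene))
        for chrom, ivs in flat.items():
            ivs.sort()
            for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping panel intervals on {chrom}: "
                        f"{g1}[{s1},{e1}) and {g2}[{s2},{e2})"
                    )

    @property
    def genes(self) -> list[str]:
        return sorted(self.intervals)

    def gene_at(self, locus: Locus) -> str | None:
        """Panel gene containing the locus (1-based position), or None."""
        pos0 = locus.pos - 1
        for start, end, gene in self._by_chrom.get(locus.chrom, ()):
            if start <= pos0 < end:
                return gene
            if start > pos0:
                break
        return None

    def coding_length(self, gene: str) -> int:
        return sum(e - s for _, s, e in self.intervals[gene])


@dataclass
class AFMatrix:
    """Samples × loci allelic-fraction matrix; 0 where a sample has no call."""

    sample_ids: list[str]
    loci: list[Locus]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"AF matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids in AF matrix")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci in AF matrix")
        if np.isnan(self.values).any():
            raise ValueError("NaN in AF matrix")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("AF values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=[str(l) for l in self.loci]
        )


# ---------------------------------------------------------------------------
# variant tables

_REQUIRED_TSV = ("sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads")


def _parse_callers(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(","))


def read_variant_table(path: str | Path, format: str | None = None) -> list[VariantCall]:
    """Read somatic calls from a TSV (internal dialect) or a VCF.

    Format is inferred from the extension when not given. Each (sample, locus)
    pair must occur at most once; multi-allelic VCF records are split into one
    call per alternate allele.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        calls = _read_variant_tsv(path)
    elif format == "vcf":
        calls = _read_variant_vcf(path)
    else:
        raise ValueError(f"unknown variant table format {format!r}")
    seen: set[tuple[str, Locus]] = set()
    for call in calls:
        key = (call.sample_id, call.locus)
        if key in seen:
            raise ValueError(
                f"duplicate record for sample {call.sample_id} at {call.locus} in {path}"
            )
        seen.add(key)
    return calls


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in _REQUIRED_TSV if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    calls: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            locus = Locus(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            depth = int(row.depth)
            alt_reads = int(row.alt_reads)
            af = getattr(row, "af", None)
            if af is None or (isinstance(af, float) and math.isnan(af)):
                af = alt_reads / depth if depth > 0 else 0.0
            gene = getattr(row, "gene", None)
            if isinstance(gene, float) and math.isnan(gene):
                gene = None
            effect = getattr(row, "effect", "unclassified")
            if isinstance(effect, float) and math.isnan(effect):
                effect = "unclassified"
            calls.append(
                VariantCall(
                    sample_id=str(row.sample_id),
                    locus=locus,
                    depth=depth,
                    alt_reads=alt_reads,
                    af=float(af),
                    callers=_parse_callers(getattr(row, "callers", None)),
                    effect=str(effect),
                    gene=None if gene is None else str(gene),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at line {i}: {exc}") from exc
    return calls


def _read_variant_vcf(path: Path) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            for sample in samples:
                sdata = rec.samples[sample]
                ad = sdata.get("AD")
                dp = sdata.get("DP")
                if ad is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {sample} "
                        "lacks AD allele-depth field"
                    )
                total = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                for alt_idx, alt in enumerate(rec.alts or (), start=1):
                    alt_reads = int(ad[alt_idx] or 0)
                    if alt_reads == 0:
                        continue
                    locus = Locus(rec.chrom, rec.pos, rec.ref, str(alt))
                    calls.append(
                        VariantCall.from_counts(sample, locus, total, alt_reads)
                    )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls in the internal TSV dialect (AF printed to full precision)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom": c.locus.chrom,
                "pos": c.locus.pos,
                "ref": c.locus.ref,
                "alt": c.locus.alt,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
                "af": repr(c.af),
                "gene": c.gene or "",
                "effect": c.effect,
                "callers": ",".join(sorted(c.callers)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets

_META_COLUMNS = ("sample_id", "patient_id", "role", "site", "stage")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read and validate the sample sheet (CSV or TSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    metas: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        role = row.role
        if role == "tumor" and not row.patient_id:
            raise ValueError(f"tumor sample {row.sample_id} has no patient_id")
        # blood samples: site/stage are irrelevant and dropped
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                role=role,
                site=(row.site or None) if role != "blood" else None,
                stage=(row.stage or None) if role != "blood" else None,
                histotype=getattr(row, "histotype", "") or None,
                grade=getattr(row, "grade", "") or None,
                pt_status=getattr(row, "pt_status", "") or "unknown",
            )
        )
    validate_sample_sheet(metas)
    return metas


def validate_sample_sheet(metas: Sequence[SampleMeta]) -> None:
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample sheet")
    bloods: dict[str, str] = {}
    for m in metas:
        if m.role == "blood":
            if m.patient_id in bloods:
                raise ValueError(
                    f"patient {m.patient_id} has two blood samples "
                    f"({bloods[m.patient_id]}, {m.sample_id})"
                )
            bloods[m.patient_id] = m.sample_id


def write_sample_sheet(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "patient_id": m.patient_id,
            "role": m.role,
            "site": m.site or "",
            "stage": m.stage or "",
            "histotype": m.histotype or "",
            "grade": m.grade or "",
            "pt_status": m.pt_status,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene panels

def read_gene_panel(bed_path: str | Path, pathway_path: str | Path) -> GenePanel:
    """Read a panel from a 4-column BED (chrom, start, end, gene) and a
    two-column gene→pathway TSV."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str, "gene": str},
    )
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for row in bed.itertuples(index=False):
        intervals.setdefault(row.gene, []).append((row.chrom, int(row.start), int(row.end)))
    pw = pd.read_csv(pathway_path, sep="\t", dtype=str)
    if not {"gene", "pathway"} <= set(pw.columns):
        pw = pd.read_csv(pathway_path, sep="\t", header=None, names=["gene", "pathway"], dtype=str)
    pathway_of = dict(zip(pw["gene"], pw["pathway"]))
    return GenePanel(intervals, pathway_of)


def write_gene_panel(panel: GenePanel, bed_path: str | Path, pathway_path: str | Path) -> None:
    rows = [
        {"chrom": c, "start": s, "end": e, "gene": g}
        for g in panel.genes
        for c, s, e in panel.intervals[g]
    ]
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", index=False, header=False)
    pd.DataFrame(
        [{"gene": g, "pathway": panel.pathway_of[g]} for g in panel.genes]
    ).to_csv(pathway_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths.

    Labels with Newick metacharacters are quoted by the writer; a
    write-then-read round trip yields an isomorphic tree with branch lengths
    preserved to 1e-6.
    """
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
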