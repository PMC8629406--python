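"""Harmonization of two callers' outputs per tumor/blood pair and somatic
filtering against the matched normal.

A tumor call passes when its coverage is at least ``min_depth`` (200x by
default, inclusive), its allelic fraction is strictly above ``min_af`` (1%),
and the locus does not look germline in the patient's matched blood. A locus
is considered germline when the blood sample shows AF above
``germline_max_af_in_blood`` with adequate blood coverage; blood coverage
below ``germline_min_blood_depth`` cannot rule germline status in or out, so
such loci are retained but flagged ``blood_low_coverage``.

Every rejected call carries exactly one primary reason, assigned in the fixed
order germline -> depth -> af, so audit summaries are deterministic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .variant_io import Locus, VariantCall

__all__ = [
    "FilterConfig",
    "FilterResult",
    "merge_callers",
    "apply_somatic_filters",
    "filter_summary",
]

REASONS = ("germline", "depth", "af")


@dataclass
class FilterConfig:
    min_depth: int = 200
    min_af: float = 0.01
    caller_mode: str = "union"
    germline_max_af_in_blood: float = 0.02
    germline_min_blood_depth: int = 50
    # optional extra per-call predicates (name, call -> keep?); a hook for
    # caller-specific quality cutoffs not modelled here
    extra_predicates: Sequence[tuple[str, Callable[[VariantCall], bool]]] = ()

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0.0 <= self.min_af < 1.0):
            raise ValueError("min_af must be in [0, 1)")
        if self.caller_mode not in ("union", "intersection"):
            raise ValueError(f"unknown caller_mode {self.caller_mode!r}")


@dataclass
class FilterResult:
    passing: list[VariantCall]
    rejected: list[tuple[VariantCall, str]]
    flagged_low_blood_coverage: list[Locus] = field(default_factory=list)

    def __iter__(self):  # allow tuple-unpacking (passing, rejected)
        yield self.passing
        yield self.rejected


def merge_callers(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
    mode: str = "union",
) -> list[VariantCall]:
    """Merge two callers' call lists for one sample.

    Union keeps every locus from either list; intersection keeps loci reported
    by both. When both report a locus, counts come from the caller with higher
    depth; caller provenance is the union of both tags.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"calls from different samples cannot be merged: {sorted(samples)}")
    by_locus_a = {c.locus: c for c in calls_a}
    by_locus_b = {c.locus: c for c in calls_b}
    if len(by_locus_a) != len(calls_a) or len(by_locus_b) != len(calls_b):
        raise ValueError("duplicate loci within one caller's call list")

    merged: list[VariantCall] = []
    loci = set(by_locus_a) | set(by_locus_b)
    for locus in sorted(loci):
        a, b = by_locus_a.get(locus), by_locus_b.get(locus)
        if a is not None and b is not None:
            best = a if a.depth >= b.depth else b
            merged.append(
                VariantCall(
                    sample_id=best.sample_id,
                    locus=locus,
                    depth=best.depth,
                    alt_reads=best.alt_reads,
                    af=best.af,
                    callers=a.callers | b.callers,
                    effect=best.effect,
                    gene=best.gene,
                )
            )
        elif mode == "union":
            merged.append(a if a is not None else b)
    return merged


def apply_somatic_filters(
    tumor_calls: Sequence[VariantCall],
    blood_calls: Sequence[VariantCall] | None,
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply coverage, AF and matched-normal germline filters to one tumor sample."""
    if cfg is None:
        cfg = FilterConfig()
    if blood_calls is None:
        raise ValueError("matched blood sample is required for somatic filtering")
    blood_samples = {c.sample_id for c in blood_calls}
    if len(blood_samples) > 1:
        raise ValueError(f"blood calls from multiple samples: {sorted(blood_samples)}")
    blood_by_locus = {c.locus: c for c in blood_calls}

    passing: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    flagged: list[Locus] = []
    for call in tumor_calls:
        blood = blood_by_locus.get(call.locus)
        germline = False
        if blood is not None:
            if blood.depth >= cfg.germline_min_blood_depth:
                germline = blood.af > cfg.germline_max_af_in_blood
            else:
                flagged.append(call.locus)
        reason = None
        if germline:
            reason = "germline"
        elif call.depth < cfg.min_depth:
            reason = "depth"
        elif not call.af > cfg.min_af:
            reason = "af"
        else:
            for name, keep in cfg.extra_predicates:
                if not keep(call):
                    reason = name
                    break
        if reason is None:
            passing.append(call)
        else:
            rejected.append((call, reason))
    if flagged:
        warnings.warn(
            f"{len(flagged)} loci retained despite blood coverage below "
            f"{cfg.germline_min_blood_depth}x (germline status unverifiable)",
            stacklevel=2,
        )
    return FilterResult(passing, rejected, flagged)


def filter_summary(rejected: Iterable[tuple[VariantCall, str]]) -> dict[str, int]:
    """Counts of rejected calls per primary reason (all standard reasons present)."""
    counts = Counter(reason for _, reason in rejected)
    out = {reason: counts.pop(reason, 0) for reason in REASONS}
    out.update(sorted(counts.items()))
    return out
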