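"""Single-base substitution spectra and pre/post-chemotherapy comparison.

Substitutions are folded onto the pyrimidine-referenced convention standard
in mutational-signature work: a G>A change is reported as its reverse
complement C>T, so every SNV falls into one of six classes (C>A, C>G, C>T,
T>A, T>C, T>G). Spectra are compared between the chemo-naive (primary
surgery) and post-chemotherapy (second/third surgery) compartments with a
chi-squared homogeneity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .variant_io import SampleMeta, VariantCall

__all__ = [
    "SUBSTITUTION_CLASSES",
    "SpectrumCounts",
    "substitution_class",
    "spectrum_by_stage",
    "compare_spectra",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-folded class of a single-base substitution."""
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumCounts:
    """Counts over the six pyrimidine-referenced substitution classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in SUBSTITUTION_CLASSES}
    )

    def __post_init__(self) -> None:
        full = {k: int(self.counts.get(k, 0)) for k in SUBSTITUTION_CLASSES}
        extra = set(self.counts) - set(SUBSTITUTION_CLASSES)
        if extra:
            raise ValueError(f"unknown substitution classes {sorted(extra)}")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, ref: str, alt: str) -> None:
        self.counts[substitution_class(ref, alt)] += 1

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[k] for k in SUBSTITUTION_CLASSES], dtype=int)


def spectrum_by_stage(
    calls: Sequence[VariantCall], meta: Sequence[SampleMeta]
) -> dict[str, SpectrumCounts]:
    """Pooled spectra for the chemo-naive and post-chemotherapy compartments.

    Primary-surgery samples contribute to ``pre_chemo``; second- and
    third-surgery samples to ``post_chemo``. Indels and multi-nucleotide
    variants are excluded.
    """
    midx = {m.sample_id: m for m in meta}
    spectra = {"pre_chemo": SpectrumCounts(), "post_chemo": SpectrumCounts()}
    for c in calls:
        m = midx.get(c.sample_id)
        if m is None or m.role != "tumor":
            continue
        if len(c.locus.ref) != 1 or len(c.locus.alt) != 1:
            continue
        stage = "pre_chemo" if m.stage == "primary" else "post_chemo"
        spectra[stage].add(c.locus.ref, c.locus.alt)
    if spectra["post_chemo"].total == 0:
        warnings.warn("no post-chemotherapy SNVs: spectrum comparison not possible",
                      stacklevel=2)
    return spectra


def compare_spectra(
    pre: SpectrumCounts, post: SpectrumCounts
) -> tuple[float, float, int]:
    """Chi-squared homogeneity test of two spectra.

    Classes with zero counts in both spectra are dropped and the degrees of
    freedom adjusted accordingly. Returns (statistic, p-value, dof).
    Identical spectra give statistic 0 and p = 1.
    """
    if pre.total == 0 or post.total == 0:
        raise ValueError("both spectra must contain at least one SNV")
    table = np.vstack([pre.as_array(), post.as_array()])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0, 0
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


def spectra_frame(spectra: Mapping[str, SpectrumCounts]) -> pd.DataFrame:
    rows = {
        name: {**s.counts, "total": s.total} for name, s in sorted(spectra.items())
    }
    df = pd.DataFrame(rows).T
    df.index.name = "stage"
    return df
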