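"""Unsupervised clustering of allelic-fraction matrices and per-patient
distance phylogenies rooted on an unrelated control.

Trees are built with neighbor-joining on pairwise AF distances. The
implementation here is deterministic: ties in the Q criterion are broken by
the smallest (row, column) taxon-index pair, and negative branch lengths
produced by NJ on non-additive matrices are clamped to zero with the deficit
moved onto the sibling branch, preserving the cherry's total length. On an
additive distance matrix NJ recovers the generating topology and branch
lengths exactly.

Absent calls are encoded as AF 0, not imputed: with matched-normal filtering
at ~2500x panel depth, absence of a call is strong evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .variant_io import AFMatrix, SampleMeta, VariantCall

__all__ = [
    "build_af_matrix",
    "ClusterResult",
    "cluster_samples",
    "DistanceMatrix",
    "af_distance",
    "neighbor_joining",
    "build_patient_tree",
    "tree_leaf_pairs",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def build_af_matrix(
    calls: Sequence[VariantCall],
    meta: Sequence[SampleMeta] | None = None,
    exclude_synonymous: bool = False,
    sample_ids: Sequence[str] | None = None,
) -> AFMatrix:
    """Samples × loci AF matrix over the union of called loci.

    Samples default to all tumor/control samples seen in the calls (or in
    ``meta``); loci are the union across selected samples, sorted; AF is 0
    where a sample has no call. Synonymous loci are dropped when requested.
    """
    if sample_ids is None:
        if meta is not None:
            sample_ids = sorted(
                m.sample_id for m in meta if m.role in ("tumor", "control")
            )
        else:
            sample_ids = sorted({c.sample_id for c in calls})
    sample_set = set(sample_ids)

    synonymous = {c.locus for c in calls if c.effect == "synonymous"}
    loci = sorted(
        {
            c.locus
            for c in calls
            if c.sample_id in sample_set
            and not (exclude_synonymous and c.locus in synonymous)
        }
    )
    if not loci:
        raise ValueError("no loci left for the AF matrix")
    locus_idx = {l: j for j, l in enumerate(loci)}
    sample_idx = {s: i for i, s in enumerate(sample_ids)}
    values = np.zeros((len(sample_ids), len(loci)))
    for c in calls:
        i = sample_idx.get(c.sample_id)
        j = locus_idx.get(c.locus)
        if i is not None and j is not None:
            values[i, j] = c.af
    return AFMatrix(list(sample_ids), loci, values)


@dataclass
class ClusterResult:
    """Agglomerative clustering of an AF matrix along both axes."""

    sample_ids: list[str]
    sample_linkage: np.ndarray
    locus_linkage: np.ndarray | None
    sample_order: list[str]
    flat_clusters: dict[str, int]  # sample -> cluster label at k=2


def cluster_samples(
    m: AFMatrix, metric: str = "euclidean", linkage: str = "average", k: int = 2
) -> ClusterResult:
    """Deterministic hierarchical clustering of samples (and loci) of an AF
    matrix, with flat sample clusters at a cut of ``k``.

    Rows are sorted lexicographically by sample id before linkage so equal
    distances resolve identically regardless of input order.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("need >= 2 samples to cluster")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(np.asarray(m.sample_ids, dtype=object))
    ids = [m.sample_ids[i] for i in order]
    values = m.values[order]
    if np.isnan(values).any():
        raise ValueError("NaN in AF matrix")
    z_samples = sch.linkage(values, method=linkage, metric=_METRICS[metric])
    z_loci = None
    if len(m.loci) >= 2:
        z_loci = sch.linkage(values.T, method=linkage, metric=_METRICS[metric])
    leaves = sch.leaves_list(z_samples)
    flat = sch.fcluster(z_samples, t=k, criterion="maxclust")
    return ClusterResult(
        sample_ids=ids,
        sample_linkage=z_samples,
        locus_linkage=z_loci,
        sample_order=[ids[i] for i in leaves],
        flat_clusters={s: int(c) for s, c in zip(ids, flat)},
    )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def af_distance(m: AFMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample distances over AF locus vectors."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    d = squareform(pdist(m.values, metric=_METRICS[metric]))
    return DistanceMatrix(list(m.sample_ids), d)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, returned with a trifurcating root).

    Deterministic: Q-matrix ties are broken by the smallest (i, j) index pair
    in the current taxon ordering. Negative branch lengths are clamped to 0
    and the deficit is transferred to the sibling branch of the join.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    dm = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.sample_ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties resolved by row-major (i, j) order
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dm[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dm = np.vstack([dm[keep][:, keep], new_row[keep][None, :]])
        dm = np.hstack([dm, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final 3-taxon star
    la = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    lb = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    lc = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, length)
    return TreeNode(children=list(nodes))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def build_patient_tree(d: DistanceMatrix, outgroup_id: str) -> TreeNode:
    """NJ tree rooted on the edge leading to the unrelated-control outgroup."""
    if outgroup_id not in d.sample_ids:
        raise ValueError(f"outgroup {outgroup_id!r} not in distance matrix")
    if len(d.sample_ids) < 3:
        raise ValueError("need >= 3 taxa including the outgroup")
    unrooted = neighbor_joining(d)
    tip = unrooted.find(outgroup_id)
    rooted = unrooted.root_at(tip, above=True, branch_attrs=[])
    for node in rooted.traverse():
        if node.length is None and not node.is_root():
            node.length = 0.0
    return rooted


def tree_leaf_pairs(
    tree: TreeNode, exclude: Sequence[str] = ()
) -> list[tuple[str, str]]:
    """All cherries of the tree: leaf pairs sharing an immediate ancestor.

    Multifurcations yield every pair of tip children. Pairs involving an
    excluded label (e.g. the outgroup) are dropped.
    """
    excluded = set(exclude)
    pairs: list[tuple[str, str]] = []
    for node in tree.non_tips(include_self=True):
        tips = sorted(c.name for c in node.children if c.is_tip())
        for a_idx in range(len(tips)):
            for b_idx in range(a_idx + 1, len(tips)):
                a, b = tips[a_idx], tips[b_idx]
                if a in excluded or b in excluded:
                    continue
                pairs.append((a, b))
    return sorted(pairs)
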