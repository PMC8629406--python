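from __future__ import annotations

import numpy as np
import pytest
from skbio import TreeNode

from ovhet.cluster_phylo import DistanceMatrix
from ovhet.clonesim import default_panel
from ovhet.variant_io import Locus, SampleMeta, VariantCall


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_call(sample_id, chrom="chr1", pos=100, ref="A", alt="T",
              depth=2500, alt_reads=875, effect="vus", gene=None):
    return VariantCall.from_counts(
        sample_id, Locus(chrom, pos, ref, alt), depth, alt_reads,
        effect=effect, gene=gene,
    )


@pytest.fixture
def tiny_cohort():
    """Two patients: P1 with ovary+omentum (one shared locus), P2 ovary only."""
    meta = [
        SampleMeta("P1-OV", "P1", "tumor", site="ovary", stage="primary"),
        SampleMeta("P1-OM", "P1", "tumor", site="omentum", stage="primary"),
        SampleMeta("P1-BL", "P1", "blood"),
        SampleMeta("P2-OV", "P2", "tumor", site="ovary", stage="primary"),
        SampleMeta("P2-OM", "P2", "tumor", site="omentum", stage="primary"),
        SampleMeta("P2-BL", "P2", "blood"),
    ]
    trunk = dict(chrom="chr1", pos=1000, ref="C", alt="T")
    calls = [
        make_call("P1-OV", **trunk, effect="non_synonymous"),
        make_call("P1-OM", **trunk, effect="non_synonymous"),
        make_call("P1-OV", pos=2000, ref="G", alt="A", effect="vus"),
        make_call("P1-OM", pos=3000, ref="T", alt="C", effect="synonymous"),
        make_call("P2-OV", chrom="chr2", pos=4000, ref="A", alt="AT", effect="indel"),
        make_call("P2-OM", chrom="chr2", pos=5000, ref="C", alt="G", effect="vus"),
    ]
    return calls, meta


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with uniform(0.1, 1) branch lengths and its exact
    path-length distance matrix — the oracle for NJ recovery tests."""
    names = [f"t{i}" for i in range(n_taxa)]

    def build(labels):
        if len(labels) == 1:
            return TreeNode(name=labels[0], length=float(rng.uniform(0.1, 1.0)))
        k = int(rng.integers(1, len(labels)))
        node = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        node.append(build(labels[:k]))
        node.append(build(labels[k:]))
        return node

    order = list(rng.permutation(names))
    root = TreeNode()
    root.append(build(order[: max(1, n_taxa // 2)]))
    root.append(build(order[max(1, n_taxa // 2):]))

    tips = {t.name: t for t in root.tips()}
    dm = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(names):
        for j in range(i + 1, n_taxa):
            d = tips[a].distance(tips[names[j]])
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(names, dm), root
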