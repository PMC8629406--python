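import numpy as np
import pandas as pd
import pytest

from ovhet.classify import label_concordant_patient
from ovhet.hetstats import (
    concordance_heatmap_matrix,
    leaf_pair_similarity,
    mutational_burden,
    per_gene_counts,
    per_pathway_counts,
)
from ovhet.variant_io import GenePanel, Locus, SampleMeta

from conftest import make_call


class TestMutationalBurden:
    def test_counts_by_effect_class(self):
        meta = [
            SampleMeta("S1", "P", "tumor", site="ovary", stage="primary"),
            SampleMeta("S2", "P", "tumor", site="omentum", stage="primary"),
            SampleMeta("P-BL", "P", "blood"),
        ]
        calls = [
            make_call("S1", pos=1, effect="non_synonymous"),
            make_call("S1", pos=2, ref="C", alt="G", effect="non_synonymous"),
            make_call("S1", pos=3, ref="G", alt="A", effect="non_synonymous"),
            make_call("S1", pos=4, ref="A", alt="AT", effect="indel"),
        ]
        burden = mutational_burden(calls, meta)
        assert burden.loc["S1", "total"] == 4
        assert burden.loc["S1", "non_synonymous"] == 3
        # a sample with zero passing calls still appears, with zeros
        assert burden.loc["S2", "total"] == 0
        # blood excluded
        assert "P-BL" not in burden.index


class TestPerGeneCounts:
    def test_counting_and_off_target(self, panel):
        gene = panel.genes[0]
        chrom, start, _ = panel.intervals[gene][0]
        meta = [
            SampleMeta("S1", "P", "tumor", site="ovary", stage="primary"),
            SampleMeta("P-BL", "P", "blood"),
        ]
        calls = [
            make_call("S1", chrom=chrom, pos=start + 1),
            make_call("S1", chrom=chrom, pos=start + 2),
            make_call("S1", chrom="chr21", pos=999_999_000),  # outside the panel
        ]
        counts = per_gene_counts(calls, panel, meta)
        assert counts.loc[gene, "ovary"] == 2
        assert counts.loc["off_target", "ovary"] == 1
        # conservation: column sums equal total calls per group
        assert counts["ovary"].sum() == len(calls)

    def test_group_by_sample(self, panel):
        meta = [
            SampleMeta("S1", "P", "tumor", site="ovary", stage="primary"),
            SampleMeta("S2", "P", "tumor", site="omentum", stage="primary"),
            SampleMeta("P-BL", "P", "blood"),
        ]
        calls = [make_call("S1", pos=5), make_call("S2", pos=5)]
        counts = per_gene_counts(calls, panel, meta, group_by="sample")
        assert list(counts.columns) == ["S1", "S2"]
        assert counts.sum().sum() == 2


class TestPerPathwayCounts:
    def test_pathway_additivity(self):
        panel = GenePanel(
            {"G1": [("chr1", 0, 100)], "G2": [("chr1", 200, 300)],
             "G3": [("chr1", 400, 500)]},
            {"G1": "HR", "G2": "HR", "G3": "OTHER"},
        )
        gene_counts = pd.DataFrame(
            {"ovary": [1, 2, 5], "synchronous": [3, 4, 6]},
            index=pd.Index(["G1", "G2", "G3"], name="gene"),
        )
        pw, _ = per_pathway_counts(gene_counts, panel)
        assert pw.loc["HR", "ovary"] == 3
        assert pw.loc["HR", "synchronous"] == 7
        assert pw.sum().sum() == gene_counts.sum().sum()

    def test_gene_without_pathway_errors(self):
        panel = GenePanel({"G1": [("chr1", 0, 100)]}, {"G1": "HR"})
        gene_counts = pd.DataFrame(
            {"ovary": [1, 1]}, index=pd.Index(["G1", "G9"], name="gene")
        )
        with pytest.raises(ValueError, match="G9"):
            per_pathway_counts(gene_counts, panel)

    def test_detects_simulated_pathway_excess(self):
        """With a 3x mutation-rate excess of one pathway in synchronous
        lesions and ample counts, the two-proportion test rejects in >= 90%
        of replicates."""
        panel = GenePanel(
            {"G1": [("chr1", 0, 100)], "G2": [("chr1", 200, 300)]},
            {"G1": "HR", "G2": "OTHER"},
        )
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            # ovary: HR at baseline 10% of 400 calls; synchronous: 30% of 400
            ovary_hr = rng.binomial(400, 0.10)
            sync_hr = rng.binomial(400, 0.30)
            gene_counts = pd.DataFrame(
                {"ovary": [ovary_hr, 400 - ovary_hr],
                 "synchronous": [sync_hr, 400 - sync_hr]},
                index=pd.Index(["G1", "G2"], name="gene"),
            )
            _, tests = per_pathway_counts(gene_counts, panel)
            if tests.loc["HR", "pvalue"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestConcordanceHeatmap:
    def test_cells_and_column_sums(self, panel):
        gene = panel.genes[0]
        chrom, start, _ = panel.intervals[gene][0]
        meta = [
            SampleMeta("A-OV", "A", "tumor", site="ovary", stage="primary"),
            SampleMeta("A-OM", "A", "tumor", site="omentum", stage="primary"),
            SampleMeta("A-BL", "A", "blood"),
        ]
        locus = dict(chrom=chrom, pos=start + 1)
        calls = [make_call("A-OV", **locus), make_call("A-OM", **locus)]
        labels = {"A": label_concordant_patient(calls, meta), "B": {}}
        matrix = concordance_heatmap_matrix(labels, panel)
        assert matrix.loc["A", gene] == 1
        assert matrix.loc["B"].sum() == 0  # patient with no concordant loci
        assert matrix[gene].sum() == 1  # column sum = cohort-wide count


class TestLeafPairSimilarity:
    UNIVERSE = {Locus("chr1", i, "A", "T") for i in range(1, 11)}

    def loci(self, positions):
        return {Locus("chr1", i, "A", "T") for i in positions}

    def test_worked_ten_locus_example(self):
        calls = {"A": self.loci(range(1, 7)), "B": self.loci(range(5, 9))}
        triple = leaf_pair_similarity("A", "B", calls, self.UNIVERSE)
        assert triple.concordant_pct == pytest.approx(20.00)
        assert triple.private_pct == pytest.approx(60.00)
        assert triple.wt_pct == pytest.approx(20.00)

    def test_identical_samples(self):
        calls = {"A": set(self.UNIVERSE), "B": set(self.UNIVERSE)}
        triple = leaf_pair_similarity("A", "B", calls, self.UNIVERSE)
        assert (triple.concordant_pct, triple.private_pct, triple.wt_pct) == (100.0, 0.0, 0.0)

    def test_disjoint_samples_covering_universe(self):
        calls = {"A": self.loci(range(1, 6)), "B": self.loci(range(6, 11))}
        triple = leaf_pair_similarity("A", "B", calls, self.UNIVERSE)
        assert triple.concordant_pct == 0.0
        assert triple.private_pct == 100.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            leaf_pair_similarity("A", "B", {}, set())

    def test_symmetry_and_sum_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            universe = self.loci(range(1, int(rng.integers(2, 40))))
            pick = lambda: {l for l in universe if rng.random() < 0.5}
            calls = {"A": pick(), "B": pick()}
            t1 = leaf_pair_similarity("A", "B", calls, universe)
            t2 = leaf_pair_similarity("B", "A", calls, universe)
            assert (t1.concordant_pct, t1.private_pct, t1.wt_pct) == (
                t2.concordant_pct, t2.private_pct, t2.wt_pct
            )
            assert t1.concordant_pct + t1.private_pct + t1.wt_pct == pytest.approx(
                100.0, abs=0.01
            )
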