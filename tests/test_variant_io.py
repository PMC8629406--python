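import numpy as np
import pytest
from skbio import TreeNode

from ovhet.variant_io import (
    AFMatrix,
    GenePanel,
    Locus,
    SampleMeta,
    VariantCall,
    read_newick,
    read_sample_sheet,
    read_variant_table,
    write_newick,
    write_variant_table,
)


class TestLocus:
    def test_identity_is_allele_aware(self):
        a = Locus("chr1", 100, "A", "T")
        assert a == Locus("chr1", 100, "A", "T")
        assert a != Locus("chr1", 100, "A", "G")
        assert a.site_key() == Locus("chr1", 100, "A", "G").site_key()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", pos=0, ref="A", alt="T"),
            dict(chrom="chr1", pos=5, ref="", alt="T"),
            dict(chrom="chr1", pos=5, ref="A", alt="N"),
            dict(chrom="chr1", pos=5, ref="A", alt="A"),
        ],
    )
    def test_invalid_loci_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Locus(**kwargs)


class TestVariantCall:
    def test_af_derived_from_counts(self):
        call = VariantCall.from_counts("S1", Locus("chr1", 100, "A", "T"), 200, 10)
        assert call.af == pytest.approx(10 / 200, abs=1e-9)

    def test_alt_reads_bounded_by_depth(self):
        with pytest.raises(ValueError):
            VariantCall("S1", Locus("chr1", 100, "A", "T"), 10, 11, 0.5)

    def test_indel_effect_requires_length_change(self):
        with pytest.raises(ValueError):
            VariantCall("S1", Locus("chr1", 100, "A", "T"), 10, 5, 0.5, effect="indel")
        ok = VariantCall("S1", Locus("chr1", 100, "A", "AT"), 10, 5, 0.5, effect="indel")
        assert ok.effect == "indel"


class TestVariantTable:
    def test_tsv_round_trip_preserves_fields(self, tmp_path):
        calls = [
            VariantCall.from_counts(
                "S1", Locus("chr1", 100, "A", "T"), 200, 10,
                callers=frozenset({"mutect"}), effect="vus", gene="TP53",
            ),
            VariantCall.from_counts(
                "S2", Locus("chr2", 7, "G", "GA"), 2500, 813, effect="indel",
            ),
        ]
        path = tmp_path / "calls.tsv"
        write_variant_table(calls, path)
        back = read_variant_table(path)
        assert len(back) == 2
        for a, b in zip(sorted(calls, key=lambda c: c.sample_id), back):
            assert a.locus == b.locus
            assert a.depth == b.depth and a.alt_reads == b.alt_reads
            assert a.af == pytest.approx(b.af, abs=1e-9)
            assert a.callers == b.callers and a.effect == b.effect and a.gene == b.gene

    def test_af_computed_when_absent(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\tdepth\talt_reads\n"
            "S1\tchr1\t100\tA\tT\t200\t10\n"
        )
        (call,) = read_variant_table(path)
        assert call.af == pytest.approx(0.05)

    def test_duplicate_sample_locus_rows_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        row = "S1\tchr1\t100\tA\tT\t200\t10\n"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\tdepth\talt_reads\n" + row + row
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_variant_table(path)

    def test_missing_depth_column_errors(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tchrom\tpos\tref\talt\n" "S1\tchr1\t100\tA\tT\n")
        with pytest.raises(ValueError, match="depth"):
            read_variant_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\tdepth\talt_reads\n"
            "S1\tchr1\t100\tA\tT\t200\t10\n"
            "S1\tchr1\t0\tA\tT\t200\t10\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_variant_table(path)

    def test_vcf_read_splits_multiallelic_and_classifies_indel(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tAT,G\t.\tPASS\t.\tDP:AD\t300:250,30,20\n"
        )
        calls = read_variant_table(vcf)
        assert {c.locus for c in calls} == {
            Locus("chr1", 100, "A", "AT"),
            Locus("chr1", 100, "A", "G"),
        }
        indel = next(c for c in calls if c.locus.alt == "AT")
        assert indel.locus.is_indel
        assert abs(len(indel.locus.ref) - len(indel.locus.alt)) < 50
        assert indel.depth == 300 and indel.alt_reads == 30


class TestSampleSheet:
    HEADER = "sample_id\tpatient_id\trole\tsite\tstage\thistotype\tgrade\tpt_status\n"

    def test_valid_rows(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            self.HEADER
            + "20724-L-OV\t20724\ttumor\tovary\tprimary\tserous\thigh\tsensitive\n"
            + "20724-BL\t20724\tblood\t\t\t\t\t\n"
        )
        metas = read_sample_sheet(path)
        assert metas[0].sample_id == "20724-L-OV"
        assert metas[0].site == "ovary" and metas[0].pt_status == "sensitive"
        # blood rows: site/stage irrelevant and accepted empty
        assert metas[1].role == "blood" and metas[1].site is None

    def test_unknown_stage_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            self.HEADER + "S1\tP1\ttumor\tovary\tfourth\tserous\thigh\tsensitive\n"
        )
        with pytest.raises(ValueError, match="stage"):
            read_sample_sheet(path)

    def test_two_bloods_for_one_patient_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            self.HEADER
            + "B1\tP1\tblood\t\t\t\t\t\n"
            + "B2\tP1\tblood\t\t\t\t\t\n"
        )
        with pytest.raises(ValueError, match="two blood"):
            read_sample_sheet(path)

    def test_tumor_without_patient_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(self.HEADER + "S1\t\ttumor\tovary\tprimary\t\t\t\n")
        with pytest.raises(ValueError, match="patient"):
            read_sample_sheet(path)


class TestGenePanel:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenePanel(
                {"A": [("chr1", 0, 100)], "B": [("chr1", 50, 150)]},
                {"A": "p", "B": "p"},
            )

    def test_gene_lookup_half_open(self, panel):
        gene = panel.genes[0]
        chrom, start, end = panel.intervals[gene][0]
        assert panel.gene_at(Locus(chrom, start + 1, "A", "T")) == gene
        assert panel.gene_at(Locus(chrom, end + 1, "A", "T")) != gene

    def test_gene_without_pathway_rejected(self):
        with pytest.raises(ValueError, match="pathway"):
            GenePanel({"A": [("chr1", 0, 100)]}, {})


class TestAFMatrix:
    def test_dimension_and_range_checks(self):
        loci = [Locus("chr1", 1, "A", "T")]
        with pytest.raises(ValueError):
            AFMatrix(["S1"], loci, np.array([[0.2, 0.3]]))
        with pytest.raises(ValueError):
            AFMatrix(["S1"], loci, np.array([[1.2]]))
        with pytest.raises(ValueError):
            AFMatrix(["S1", "S1"], loci + [Locus("chr1", 2, "A", "T")],
                     np.zeros((2, 2)))


class TestNewick:
    def test_two_leaf_tree_serialization(self, tmp_path):
        tree = TreeNode.read(["(A:1.0,B:2.0);"])
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text == "(A:1.0,B:2.0);"

    def test_round_trip_is_isomorphic_with_lengths(self, tmp_path):
        tree = TreeNode.read(["((A:1.5,B:0.25):0.1,(C:2.0,D:0.5):0.3);"])
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.compare_rfd(tree) == 0
        for name in "ABCD":
            assert back.find(name).length == pytest.approx(
                tree.find(name).length, abs=1e-6
            )

    def test_hyphenated_sample_label_survives(self, tmp_path):
        tree = TreeNode.read(["(20995-STO-2ME:1.0,X:2.0);"])
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert "20995-STO-2ME" in {t.name for t in read_newick(path).tips()}

    def test_duplicate_leaf_labels_rejected(self, tmp_path):
        tree = TreeNode.read(["(A:1.0,A:2.0);"])
        with pytest.raises(ValueError, match="duplicate"):
            write_newick(tree, tmp_path / "t.nwk")
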