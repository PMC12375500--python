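import numpy as np
import pandas as pd
import pytest

from rbpomics import iolib
from rbpomics.iolib import (
    ClusterRecord,
    CountMatrix,
    GenomicInterval,
    ParseError,
    SampleDesign,
)


class TestGenomicInterval:
    def test_valid(self):
        iv = GenomicInterval("chr1", 100, 150, "+")
        assert len(iv) == 50

    @pytest.mark.parametrize(
        "args",
        [("chr1", 150, 100, "+"), ("chr1", 100, 100, "+"),
         ("chr1", -1, 100, "+"), ("chr1", 0, 10, "x")],
    )
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            GenomicInterval(*args)

    def test_overlap_respects_strand(self):
        a = GenomicInterval("chr1", 0, 100, "+")
        b = GenomicInterval("chr1", 50, 150, "-")
        c = GenomicInterval("chr1", 50, 150, ".")
        assert a.overlap(b) == 0
        assert a.overlap(c) == 50

    def test_one_based_conversion(self):
        assert iolib.to_zero_based(1, 10) == (0, 10)


class TestClusterRecord:
    def test_intergenic_iff_no_gene(self):
        iv = GenomicInterval("chr1", 0, 50)
        ClusterRecord(iv, "c1")  # unannotated: intergenic, no gene
        ClusterRecord(iv, "c2", gene_id="G1", region="3UTR")
        with pytest.raises(ValueError):
            ClusterRecord(iv, "c3", gene_id="G1", region="intergenic")
        with pytest.raises(ValueError):
            ClusterRecord(iv, "c4", gene_id="", region="CDS")


class TestBed:
    def test_parse_bed6_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t150\tpk1\t0\t+\n")
        (rec,) = iolib.read_bed(p)
        assert rec.interval == GenomicInterval("chr1", 100, 150, "+")
        assert rec.cluster_id == "pk1"

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t150\tpk1\t0\t+\nchr1\t150\t100\tpk2\n")
        with pytest.raises(ParseError, match="line 2"):
            iolib.read_bed(p)

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ParseError, match="3 columns"):
            iolib.read_bed(p)

    def test_round_trip_50_records(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(50):
            start = int(rng.integers(0, 10_000))
            recs.append(
                ClusterRecord(
                    GenomicInterval(
                        f"chr{rng.integers(1, 6)}", start,
                        start + int(rng.integers(1, 400)),
                        str(rng.choice(["+", "-", "."])),
                    ),
                    cluster_id=f"pk{i}",
                    score=float(rng.integers(0, 1000)),
                    extra=(str(rng.integers(0, 9)),),
                )
            )
        p = tmp_path / "rt.bed"
        iolib.write_bed(recs, p)
        assert iolib.read_bed(p) == recs


class TestCountMatrix:
    def _write(self, tmp_path, matrix_text, design_rows):
        mp = tmp_path / "m.tsv"
        mp.write_text(matrix_text)
        dp = tmp_path / "d.tsv"
        header = "sample_id\tassay\ttreatment\treplicate\tlibrary_size\n"
        dp.write_text(header + "".join(design_rows))
        return mp, dp

    def test_read_matrix_with_design(self, tmp_path):
        samples = [f"s{i}" for i in range(8)]
        lines = ["feature_id\t" + "\t".join(samples)]
        for j in range(3):
            lines.append(f"c{j}\t" + "\t".join(str(j + i) for i in range(8)))
        rows = []
        for i, s in enumerate(samples):
            assay = "IP" if i < 4 else "input"
            trt = "treated" if i % 2 else "untreated"
            rows.append(f"{s}\t{assay}\t{trt}\t{i // 2 + 1}\t1000000\n")
        mp, dp = self._write(tmp_path, "\n".join(lines) + "\n", rows)
        cm, design = iolib.read_count_matrix(mp, dp)
        assert cm.shape == (3, 8)
        assert [d.sample_id for d in design] == samples

    def test_missing_sample_in_design(self, tmp_path):
        mp, dp = self._write(
            tmp_path,
            "feature_id\ts1\ts2\nc1\t1\t2\n",
            ["s1\tIP\ttreated\t1\t1000\n"],
        )
        with pytest.raises(ValueError, match="missing from design"):
            iolib.read_count_matrix(mp, dp)

    @pytest.mark.parametrize("bad", ["-4", "1.5"])
    def test_bad_count_rejected(self, tmp_path, bad):
        mp, dp = self._write(
            tmp_path,
            f"feature_id\ts1\nc1\t{bad}\n",
            ["s1\tIP\ttreated\t1\t1000\n"],
        )
        with pytest.raises(ValueError):
            iolib.read_count_matrix(mp, dp)

    def test_duplicate_row_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CountMatrix(["a", "a"], ["s1"], np.array([[1], [2]]))

    def test_matrix_round_trip(self, tmp_path, eclip_sim):
        p = tmp_path / "counts.tsv"
        iolib.write_count_matrix(eclip_sim.counts, p)
        df = iolib.read_tsv(p, index_col=0)
        assert (df.to_numpy() == eclip_sim.counts.values).all()


class TestDesign:
    def test_round_trip(self, tmp_path, eclip_sim):
        p = tmp_path / "design.tsv"
        iolib.write_design(eclip_sim.design, p)
        assert iolib.read_design(p) == eclip_sim.design

    def test_duplicate_cell_rejected(self, tmp_path):
        p = tmp_path / "design.tsv"
        row = "s{}\tIP\ttreated\t1\t1000\n"
        p.write_text(
            "sample_id\tassay\ttreatment\treplicate\tlibrary_size\n"
            + row.format(1) + row.format(2)
        )
        with pytest.raises(ValueError, match="duplicate"):
            iolib.read_design(p)

    def test_validation(self):
        with pytest.raises(ValueError):
            SampleDesign("s", "IP", "treated", 1, 0)
        with pytest.raises(ValueError):
            SampleDesign("s", "RIP", "treated", 1, 10)


class TestGmt:
    def test_parse_and_dedup(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("WNT\tdesc\tWNT5A\tCTNNB1\nDUP\tdesc\tA\tA\n")
        sets = iolib.read_gmt(p)
        assert sets[0].members == {"WNT5A", "CTNNB1"}
        assert sets[1].members == {"A"}

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("X\tdesc\n")
        with pytest.raises(ParseError):
            iolib.read_gmt(p)

    def test_round_trip(self, tmp_path):
        sets = [iolib.GeneSet("S1", "d1", frozenset({"A", "B"})),
                iolib.GeneSet("S2", "d2", frozenset({"C"}))]
        p = tmp_path / "rt.gmt"
        iolib.write_gmt(sets, p)
        assert iolib.read_gmt(p) == sets


class TestAnnotationAndMelt:
    def test_annotation_round_trip(self, tmp_path, eclip_sim):
        p = tmp_path / "ann.tsv"
        iolib.write_annotation(eclip_sim.annotation, p)
        back = iolib.read_annotation(p)
        assert back == eclip_sim.annotation

    def test_melt_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"temperature": [37.0, 40.0], "fraction": [1.0, 0.9],
             "condition": ["vehicle", "vehicle"], "replicate": [1, 1]}
        )
        p = tmp_path / "melt.csv"
        iolib.write_melt_csv(df, p)
        pd.testing.assert_frame_equal(iolib.read_melt_csv(p), df)
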