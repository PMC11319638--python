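import numpy as np
import pandas as pd
import pytest

import transpec as tp
from transpec.exceptions import FormatError, ValidationError


class TestExpressionIO:
    def test_tsv_identity(self, tmp_path):
        values = np.array([[1.0, 0.0], [0.5, 2.0], [0.0, 0.0]])
        expr = tp.ExpressionMatrix(values, ["a", "b", "c"], ["s1", "s2"])
        path = tmp_path / "m.tsv"
        tp.write_expression(str(path), expr)
        back = tp.read_expression(str(path))
        assert back.shape == (3, 2)
        assert back == expr

    @pytest.mark.parametrize("fmt", ["gct", "tsv"])
    def test_round_trip_preserves_values(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        expr = tp.ExpressionMatrix(
            rng.lognormal(1.0, 2.0, (20, 7)),
            [f"tx{i}" for i in range(20)],
            [f"s{i}" for i in range(7)],
        )
        path = tmp_path / f"m.{fmt}"
        tp.write_expression(str(path), expr, format=fmt)
        back = tp.read_expression(str(path), format=fmt)
        assert list(back.transcript_ids) == list(expr.transcript_ids)
        assert list(back.sample_ids) == list(expr.sample_ids)
        assert np.allclose(back.values, expr.values, rtol=1e-12, atol=0)

    def test_gct_header_row_count_mismatch(self, tmp_path):
        path = tmp_path / "bad.gct"
        body = "Name\tDescription\ts1\ts2\n" + "".join(
            f"t{i}\tna\t1.0\t2.0\n" for i in range(4)
        )
        path.write_text("#1.2\n5\t2\n" + body)
        with pytest.raises(FormatError, match="5"):
            tp.read_expression(str(path), format="gct")

    def test_gct_bad_version_line(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.3\n1\t1\nName\tDescription\ts1\nt1\tna\t1.0\n")
        with pytest.raises(FormatError, match="#1.3"):
            tp.read_expression(str(path))

    def test_gct_preserves_description(self, tmp_path):
        path = tmp_path / "m.gct"
        path.write_text("#1.2\n1\t2\nName\tDescription\ts1\ts2\nt1\tsome gene\t1.0\t0.0\n")
        expr = tp.read_expression(str(path))
        assert list(expr.description) == ["some gene"]

    def test_duplicate_transcript_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\ts1\nt1\t1.0\nt1\t2.0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            tp.read_expression(str(path))

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            tp.ExpressionMatrix([[-1.0]], ["t1"], ["s1"])


class TestSampleTable:
    def test_read_two_rows(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\ttissue\trin\ns1\tliver\t8.2\ns2\tbrain\t6.0\n")
        table = tp.read_sample_table(str(path))
        assert len(table) == 2
        assert table.tissues == ["brain", "liver"]

    def test_header_case_insensitive(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("Sample_ID\tTissue\tRIN\ns1\tliver\t8.2\n")
        assert len(tp.read_sample_table(str(path))) == 1

    def test_missing_rin_column(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\ttissue\ns1\tliver\n")
        with pytest.raises(ValidationError, match="rin"):
            tp.read_sample_table(str(path))

    def test_rin_out_of_range(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("sample_id\ttissue\trin\ns1\tliver\t11\n")
        with pytest.raises(ValidationError, match=r"\[1, 10\]"):
            tp.read_sample_table(str(path))


class TestAnnotationIO:
    def _write(self, tmp_path, rows):
        path = tmp_path / "a.gtf"
        path.write_text("".join(rows))
        return str(path)

    @staticmethod
    def _row(chrom, start, end, strand, gene, tx):
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        return f"{chrom}\tx\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"

    def test_single_transcript_coordinates_one_based(self, tmp_path):
        path = self._write(tmp_path, [self._row("chr1", 1000, 5000, "+", "G1", "T1")])
        ann = tp.read_annotation(path)
        rec = ann.df.iloc[0]
        assert (rec.chrom, rec.start, rec.end, rec.strand) == ("chr1", 1000, 5000, "+")

    def test_shared_gene_id(self, tmp_path):
        path = self._write(
            tmp_path,
            [self._row("chr1", 1000, 5000, "+", "G1", "T1"),
             self._row("chr1", 2000, 6000, "+", "G1", "T2")],
        )
        ann = tp.read_annotation(path)
        assert list(ann.df["gene_id"]) == ["G1", "G1"]

    def test_dot_strand_rejected(self, tmp_path):
        path = self._write(tmp_path, [self._row("chr1", 1, 10, ".", "G1", "T1")])
        with pytest.raises(ValidationError, match="strand"):
            tp.read_annotation(path)

    def test_missing_transcript_id_rejected(self, tmp_path):
        row = 'chr1\tx\ttranscript\t1\t10\t.\t+\t.\tgene_id "G1";\n'
        path = self._write(tmp_path, [row])
        with pytest.raises(ValidationError, match="transcript_id"):
            tp.read_annotation(path)

    def test_annotation_round_trip(self, tmp_path):
        ann = tp.AnnotationTable(pd.DataFrame({
            "transcript_id": ["T1", "T2"], "gene_id": ["G1", "G1"],
            "chrom": ["chr2", "chr2"], "start": [100, 7000],
            "end": [900, 9000], "strand": ["+", "-"],
        }))
        path = tmp_path / "a.gtf"
        tp.write_annotation(str(path), ann)
        back = tp.read_annotation(str(path))
        pd.testing.assert_frame_equal(
            back.df.sort_values("transcript_id").reset_index(drop=True),
            ann.df.sort_values("transcript_id").reset_index(drop=True),
        )


class TestResultsIO:
    def _result_and_stats(self, n=2):
        probs = tp.ProbabilityTable(
            np.tile([0.9, 0.1], (n, 1)), [f"tx{i}" for i in range(n)], ["A", "B"]
        )
        thr = pd.DataFrame(
            {"rip": [0.8, 0.8], "lip": [0.1, 0.1], "rip_fallback": False,
             "lip_fallback": False, "bandwidth": 0.05},
            index=pd.Index(["A", "B"], name="tissue"),
        )
        frame = pd.DataFrame({
            "transcript_id": [f"tx{i}" for i in range(n)],
            "tissues": "A", "fc_max": 2.0, "emp_p": 0.01,
        })
        tau = pd.Series(0.9, index=frame["transcript_id"])
        stats = tp.SpecificityStats(frame, tau, n_iterations=99, seed=0)
        result = tp.classify(probs, thr, stats)
        return result, stats

    def test_row_count_and_read_back(self, tmp_path):
        result, stats = self._result_and_stats(2)
        path = tmp_path / "r.tsv"
        tp.write_results(str(path), result, stats)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3  # header + 2 rows
        back = tp.read_results(str(path))
        assert list(back["class"]) == list(
            result.frame.sort_values("transcript_id")["class"]
        )

    def test_mismatched_transcript_sets(self, tmp_path):
        result, stats = self._result_and_stats(2)
        bad_tau = pd.Series(0.5, index=["tx0", "other"])
        bad = tp.SpecificityStats(stats.frame, bad_tau, n_iterations=99, seed=0)
        with pytest.raises(ValidationError, match="transcript sets"):
            tp.write_results(str(tmp_path / "r.tsv"), result, bad)

    def test_empty_result_header_only(self, tmp_path):
        probs = tp.ProbabilityTable(np.empty((0, 2)), [], ["A", "B"])
        thr = pd.DataFrame(
            {"rip": [0.8, 0.8], "lip": [0.1, 0.1], "rip_fallback": False,
             "lip_fallback": False, "bandwidth": 0.05},
            index=pd.Index(["A", "B"], name="tissue"),
        )
        stats = tp.SpecificityStats(
            pd.DataFrame(columns=["transcript_id", "tissues", "fc_max", "emp_p"]),
            pd.Series(dtype=float), n_iterations=99, seed=0,
        )
        result = tp.classify(probs, thr, stats)
        path = tmp_path / "r.tsv"
        tp.write_results(str(path), result, stats)
        lines = [l for l in path.read_text().strip().split("\n") if l]
        assert len(lines) == 1
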