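"""Summary-statistics parsing, Z-score conversions and SNP alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sclc.sumstats import (
    SummaryStatsTable,
    SumstatsError,
    adjusted_z,
    align_z_matrix,
    read_ldscores,
    read_sumstats,
    score_statistic,
    write_results,
    z_from_beta,
)
from sclc.clc import TestResult as Result

from conftest import write_sumstats_file


class TestReadSumstats:
    def test_default_dialect(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.sumstats",
            [["rs1", 1, 100, "A", "G", 1.5, 1000],
             ["rs2", 1, 200, "C", "T", -0.5, 1000],
             ["rs3", 2, 300, "A", "C", 0.0, 1000]],
        )
        t = read_sumstats(path, phenotype_id="a")
        assert t.n_snps == 3
        assert list(t.data["snp"]) == ["rs1", "rs2", "rs3"]
        assert t.z_scores().tolist() == [1.5, -0.5, 0.0]
        assert t.mean_n() == 1000

    def test_beta_se_without_z(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "b.sumstats",
            [["rs1", "A", "G", 0.1, 0.05], ["rs2", "C", "T", -0.2, 0.1]],
            header="SNP A1 A2 BETA SE",
        )
        t = read_sumstats(path)
        assert "z" not in t.data.columns
        np.testing.assert_allclose(t.z_scores(), [2.0, -2.0])

    def test_duplicate_snp_rejected(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "c.sumstats",
            [["rs1", "A", "G", 1.0], ["rs1", "A", "G", 2.0]],
            header="SNP A1 A2 Z",
        )
        with pytest.raises(SumstatsError, match="rs1"):
            read_sumstats(path)

    def test_malformed_numeric_named_with_line(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "d.sumstats",
            [["rs1", "A", "G", 1.0], ["rs2", "A", "G", "oops"]],
            header="SNP A1 A2 Z",
        )
        with pytest.raises(SumstatsError, match="line 3"):
            read_sumstats(path)

    def test_empty_file_and_missing_column(self, tmp_path):
        empty = tmp_path / "e.sumstats"
        empty.write_text("")
        with pytest.raises(SumstatsError):
            read_sumstats(empty)
        path = write_sumstats_file(tmp_path / "f.sumstats", [["1", "2"]], header="FOO BAR")
        with pytest.raises(SumstatsError, match="SNP"):
            read_sumstats(path)

    def test_custom_dialect(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "g.sumstats", [["rs1", 2.5]], header="variant zscore"
        )
        t = read_sumstats(path, dialect={"snp": "variant", "z": "zscore"})
        assert t.z_scores().tolist() == [2.5]


class TestLdscores:
    def test_ldsc_dialect(self, tmp_path):
        path = tmp_path / "chr1.l2.ldscore"
        path.write_text("CHR\tSNP\tBP\tL2\n1\trs1\t100\t3.5\n1\trs2\t200\t1.0\n")
        df = read_ldscores(path)
        assert df["ldscore"].tolist() == [3.5, 1.0]

    def test_gzip_transparent(self, tmp_path):
        import gzip

        path = tmp_path / "chr1.l2.ldscore.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("CHR SNP BP L2\n1 rs1 100 2.0\n")
        assert read_ldscores(path)["ldscore"].tolist() == [2.0]


class TestConversions:
    @pytest.mark.parametrize(
        "beta,se,expected", [(0.1, 0.05, 2.0), (0.0, 1.0, 0.0), (-0.3, 0.1, -3.0)]
    )
    def test_z_from_beta(self, beta, se, expected):
        assert z_from_beta(beta, se) == pytest.approx(expected)

    def test_z_from_beta_rejects_bad_se(self):
        with pytest.raises(ValueError):
            z_from_beta(1.0, 0.0)

    def test_z_from_beta_scale_invariant(self, rng):
        beta, se = rng.normal(), rng.uniform(0.01, 1)
        for c in (0.1, 3.0, 1e6):
            assert z_from_beta(c * beta, c * se) == pytest.approx(z_from_beta(beta, se))

    @pytest.mark.parametrize(
        "p,sign,expected",
        [
            (1.0, 1, 0.0),
            (0.05, 1, 1.959964),  # sqrt of the 95th percentile of chi2_1
            (0.3173105, -1, -1.0000),
        ],
    )
    def test_adjusted_z_examples(self, p, sign, expected):
        assert adjusted_z(p, sign) == pytest.approx(expected, abs=1e-4)

    @given(z=st.floats(min_value=-40, max_value=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_adjusted_z_round_trip(self, z):
        """Two-sided p of Z, fed back through adjusted_z, returns Z.

        Beyond |Z| ~ 38 the two-sided p underflows double precision, so the
        round trip goes through the log-scale path there.
        """
        sign = 1 if z >= 0 else -1
        log10p = (np.log(2) + stats.norm.logsf(abs(z))) / np.log(10)
        assert adjusted_z(log10p=log10p, sign=sign) == pytest.approx(z, rel=1e-8, abs=1e-8)
        if abs(z) < 37:
            p = 2 * stats.norm.sf(abs(z))
            assert adjusted_z(p, sign) == pytest.approx(z, rel=1e-8, abs=1e-8)

    def test_adjusted_z_log_scale_path(self):
        # p = 1e-320 underflows nothing here; check against the direct path
        z = adjusted_z(log10p=-320.0, sign=1)
        assert 38 < z < 39
        # consistency where both paths work
        assert adjusted_z(log10p=np.log10(0.05), sign=1) == pytest.approx(
            adjusted_z(0.05, 1), rel=1e-12
        )

    def test_adjusted_z_rejects_zero_p(self):
        with pytest.raises(ValueError):
            adjusted_z(0.0, 1)


class TestScoreStatistic:
    @pytest.mark.parametrize(
        "y,g,expected",
        [
            ((1, 0, 1, 0), (2, 0, 1, 1), 1.0),
            ((1, 1, 1), (5, -2, 9), 0.0),
            ((1, 0), (1, 0), 0.5),
        ],
    )
    def test_examples(self, y, g, expected):
        assert score_statistic(y, g) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_statistic([1, 0], [1, 0, 1])


def _table(pid, rows, cols=("snp", "a1", "a2", "z")):
    return SummaryStatsTable(pid, pd.DataFrame([dict(zip(cols, r)) for r in rows]))


class TestAlignZMatrix:
    def test_intersection(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0), ("rs2", "C", "T", 2.0), ("rs3", "A", "C", 3.0)])
        t2 = _table("p2", [("rs1", "A", "G", 0.5), ("rs3", "A", "C", -1.0)])
        zm = align_z_matrix([t1, t2])
        assert zm.snp_ids == ["rs1", "rs3"]
        np.testing.assert_allclose(zm.values, [[1.0, 3.0], [0.5, -1.0]])

    def test_swapped_alleles_flip_sign(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0), ("rs2", "C", "T", 2.0)])
        t2 = _table("p2", [("rs1", "G", "A", 0.5), ("rs2", "C", "T", -1.0)])
        zm = align_z_matrix([t1, t2])
        np.testing.assert_allclose(zm.values[1], [-0.5, -1.0])
        assert zm.report.n_sign_flipped == 1

    def test_incompatible_alleles_dropped_and_counted(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0), ("rs2", "C", "T", 2.0)])
        t2 = _table("p2", [("rs1", "A", "G", 0.5), ("rs2", "A", "G", -1.0)])
        zm = align_z_matrix([t1, t2])
        assert zm.snp_ids == ["rs1"]
        assert zm.report.n_dropped_incompatible == 1

    def test_strand_ambiguous_flagged(self):
        t1 = _table("p1", [("rs1", "A", "T", 1.0), ("rs2", "C", "T", 2.0)])
        t2 = _table("p2", [("rs1", "A", "T", 0.5), ("rs2", "C", "T", -1.0)])
        zm = align_z_matrix([t1, t2])
        assert zm.report.ambiguous_snps == ["rs1"]
        assert zm.M == 2  # kept, only flagged

    def test_disjoint_snps_error(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0)])
        t2 = _table("p2", [("rs9", "A", "G", 1.0)])
        with pytest.raises(SumstatsError, match="intersection"):
            align_z_matrix([t1, t2])

    def test_order_insensitive_up_to_row_order(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0), ("rs2", "C", "T", 2.0)])
        t2 = _table("p2", [("rs2", "C", "T", -1.0), ("rs1", "A", "G", 0.5)])
        zm12 = align_z_matrix([t1, t2])
        zm21 = align_z_matrix([t2, t1])
        for pid in ("p1", "p2"):
            i, j = zm12.phenotype_ids.index(pid), zm21.phenotype_ids.index(pid)
            a = dict(zip(zm12.snp_ids, zm12.values[i]))
            b = dict(zip(zm21.snp_ids, zm21.values[j]))
            assert a == b

    def test_ldscore_restriction(self):
        t1 = _table("p1", [("rs1", "A", "G", 1.0), ("rs2", "C", "T", 2.0)])
        t2 = _table("p2", [("rs1", "A", "G", 0.5), ("rs2", "C", "T", -1.0)])
        ld = pd.DataFrame({"snp": ["rs2"], "ldscore": [3.0]})
        zm = align_z_matrix([t1, t2], ld)
        assert zm.snp_ids == ["rs2"]
        np.testing.assert_allclose(zm.ldscores, [3.0])


class TestWriteResults:
    def test_layout_and_p_format(self, tmp_path):
        res = {
            "rs1": [Result("sclc", 1.0, 0.5), Result("wald", 2.0, 3.2e-7)],
            "rs2": [Result("sclc", 0.1, 0.9), Result("wald", 0.2, 0.8)],
        }
        out = tmp_path / "res.tsv"
        write_results(res, out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["SNP", "sclc_stat", "sclc_p", "wald_stat", "wald_p"]
        assert len(lines) == 3
        assert "3.200000e-07" in lines[1]

    def test_empty_results_header_only(self, tmp_path):
        out = tmp_path / "res.tsv"
        write_results({}, out)
        assert out.read_text() == "SNP\n"
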