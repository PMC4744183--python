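"""Coverage filtering, gene-body pooling, and the two-proportion z-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylscreen.dml import (
    filter_covered,
    pool_by_gene,
    report_dml,
    two_proportion_ztest,
    ztest_frame,
)
from methylscreen.genes import GeneModel
from conftest import pearson_chi2


def _table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                       "meth_count", "unmeth_count", "context"])


def _gene(gene_id, start, end, chrom="chr1"):
    return GeneModel(gene_id, chrom, "+", start, end, start, end, (start,), (end,))


class TestFilterCovered:
    def test_dual_condition_threshold(self):
        a = _table([("chr1", 10, "+", 4, 5, "CpG"),    # 9x in A -> dropped
                    ("chr1", 20, "+", 5, 5, "CpG")])   # 10x in both -> kept
        b = _table([("chr1", 10, "+", 25, 25, "CpG"),
                    ("chr1", 20, "+", 3, 7, "CpG")])
        out = filter_covered(a, b, min_cov=10)
        assert out["pos"].tolist() == [20]

    def test_sites_absent_from_one_condition_dropped(self):
        a = _table([("chr1", 10, "+", 10, 10, "CpG")])
        b = _table([("chr1", 99, "+", 10, 10, "CpG")])
        assert filter_covered(a, b).empty

    def test_strand_clash_hard_error(self):
        a = _table([("chr1", 10, "+", 10, 10, "CpG")])
        b = _table([("chr1", 10, "-", 10, 10, "CpG")])
        with pytest.raises(ValueError, match="inconsistent strand"):
            filter_covered(a, b)

    def test_replicates_summed_before_filtering(self):
        a1 = _table([("chr1", 10, "+", 3, 3, "CpG")])
        a2 = _table([("chr1", 10, "+", 2, 2, "CpG")])
        b = _table([("chr1", 10, "+", 6, 6, "CpG")])
        out = filter_covered([a1, a2], b, min_cov=10)
        assert out["meth_count_a"].tolist() == [5]

    def test_matches_set_intersection_oracle(self, rng):
        pos_a = rng.choice(1000, size=200, replace=False)
        pos_b = rng.choice(1000, size=200, replace=False)
        a = _table([("chr1", int(p), "+", int(rng.integers(0, 20)),
                     int(rng.integers(0, 20)), "CpG") for p in sorted(pos_a)])
        b = _table([("chr1", int(p), "+", int(rng.integers(0, 20)),
                     int(rng.integers(0, 20)), "CpG") for p in sorted(pos_b)])
        out = filter_covered(a, b, min_cov=10)
        # brute force
        da = {r.pos: (r.meth_count, r.unmeth_count) for r in a.itertuples()}
        db = {r.pos: (r.meth_count, r.unmeth_count) for r in b.itertuples()}
        want = sorted(p for p in set(da) & set(db)
                      if sum(da[p]) >= 10 and sum(db[p]) >= 10)
        assert sorted(out["pos"]) == want


class TestPoolByGene:
    def test_pooling_arithmetic(self):
        a = _table([("chr1", 101, "+", 8, 2, "CpG"),
                    ("chr1", 150, "+", 6, 4, "CpG")])
        b = _table([("chr1", 101, "+", 5, 5, "CpG"),
                    ("chr1", 150, "+", 5, 5, "CpG")])
        pooled = pool_by_gene(filter_covered(a, b, min_cov=10),
                              [_gene("g1", 50, 500)])
        row = pooled.iloc[0]
        assert (row.x1, row.n1) == (6, 20)  # summed conversions / totals
        assert (row.x2, row.n2) == (10, 20)

    def test_site_outside_gene_bodies_ignored(self):
        a = _table([("chr1", 9999, "+", 10, 10, "CpG")])
        pooled = pool_by_gene(filter_covered(a, a), [_gene("g1", 50, 500)])
        assert pooled.empty

    def test_matches_interval_assignment_oracle(self, rng):
        genes = [_gene(f"g{i}", int(s), int(s) + 300)
                 for i, s in enumerate(rng.choice(5000, size=10, replace=False))]
        rows = []
        for p in sorted(rng.choice(6000, size=300, replace=False)):
            rows.append(("chr1", int(p) + 1, "+", int(rng.integers(5, 20)),
                         int(rng.integers(5, 20)), "CpG"))
        t = _table(rows)
        pooled = pool_by_gene(filter_covered(t, t), genes)
        got = {r.gene_id: (r.x1, r.n1) for r in pooled.itertuples()}
        for g in genes:
            x = n = 0
            for r in t.itertuples():
                if g.tx_start <= r.pos - 1 < g.tx_end:
                    x += r.unmeth_count
                    n += r.meth_count + r.unmeth_count
            if n:
                assert got[g.gene_id] == (x, n)
            else:
                assert g.gene_id not in got


class TestZTest:
    def test_identical_proportions(self):
        assert two_proportion_ztest(5, 10, 5, 10) == (0.0, 1.0)

    def test_worked_example(self):
        z, p = two_proportion_ztest(90, 100, 50, 100)
        assert z == pytest.approx(6.1721, abs=1e-3)
        assert z ** 2 == pytest.approx(pearson_chi2(90, 100, 50, 100), rel=1e-9)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_degenerate_tables(self):
        assert two_proportion_ztest(0, 50, 0, 80) == (0.0, 1.0)
        assert two_proportion_ztest(50, 50, 80, 80) == (0.0, 1.0)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(1, 200, size=2)
            x1 = rng.integers(0, n1 + 1)
            x2 = rng.integers(0, n2 + 1)
            z1, p1 = two_proportion_ztest(x1, n1, x2, n2)
            z2, p2 = two_proportion_ztest(x2, n2, x1, n1)
            assert z1 == pytest.approx(-z2)
            assert p1 == pytest.approx(p2)

    def test_chi_square_equivalence_random_tables(self, rng):
        checked = 0
        while checked < 300:
            n1, n2 = (int(v) for v in rng.integers(2, 500, size=2))
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            pooled = (x1 + x2) / (n1 + n2)
            if pooled in (0.0, 1.0):
                continue
            z, _ = two_proportion_ztest(x1, n1, x2, n2)
            assert z ** 2 == pytest.approx(pearson_chi2(x1, n1, x2, n2), rel=1e-9)
            checked += 1

    def test_against_scipy_contingency(self, rng):
        for _ in range(50):
            n1, n2 = (int(v) for v in rng.integers(5, 300, size=2))
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(1, n2))
            z, p = two_proportion_ztest(x1, n1, x2, n2)
            chi2, p_chi, _, _ = stats.chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False)
            assert z ** 2 == pytest.approx(chi2, rel=1e-9)
            assert p == pytest.approx(p_chi, rel=1e-9)

    def test_pooling_associativity(self):
        """Merging two sites then testing equals testing pre-summed counts."""
        z_merged, _ = two_proportion_ztest(6 + 3, 20 + 10, 10 + 2, 20 + 10)
        z_direct, _ = two_proportion_ztest(9, 30, 12, 30)
        assert z_merged == z_direct

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(1, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_ztest(11, 10, 1, 10)

    def test_vectorised_frame_matches_scalar(self, rng):
        rows = []
        for i in range(40):
            n1, n2 = (int(v) for v in rng.integers(1, 100, size=2))
            rows.append((f"g{i}", int(rng.integers(0, n1 + 1)), n1,
                         int(rng.integers(0, n2 + 1)), n2))
        frame = ztest_frame(pd.DataFrame(rows, columns=["gene_id", "x1", "n1", "x2", "n2"]))
        for r in frame.itertuples():
            z, p = two_proportion_ztest(r.x1, r.n1, r.x2, r.n2)
            assert r.z == pytest.approx(z)
            assert r.p_value == pytest.approx(p)


class TestReport:
    def _results(self):
        pooled = pd.DataFrame(
            [("gA", 180, 200, 60, 200), ("gB", 100, 200, 95, 200)],
            columns=["gene_id", "x1", "n1", "x2", "n2"])
        return ztest_frame(pooled)

    def test_significance_flag_and_order(self):
        rep = report_dml(self._results(), alpha_meth=1e-4)
        assert rep.iloc[0]["gene_id"] == "gA"
        assert rep["significant"].tolist() == [True, False]

    def test_alpha_one_flags_everything(self):
        rep = report_dml(self._results(), alpha_meth=1.0)
        assert rep["significant"].all()

    def test_empty_input_status(self):
        rep = report_dml(pd.DataFrame(columns=["gene_id", "p_value"]))
        assert rep.empty
        assert "empty" in rep.attrs["status"]

    def test_fold_change_on_methylated_fraction(self):
        rep = report_dml(self._results())
        row = rep[rep["gene_id"] == "gA"].iloc[0]
        assert row["meth_frac_a"] == pytest.approx(0.1)
        assert row["meth_frac_b"] == pytest.approx(0.7)
        assert row["meth_fold_change"] == pytest.approx(7.0)

    def test_fdr_flag(self):
        rep = report_dml(self._results(), alpha_meth=0.05, fdr=True)
        assert "q_value" in rep.columns
        assert (rep["q_value"] >= rep["p_value"] - 1e-15).all()
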