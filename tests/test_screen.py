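"""Gene screen: LFC, expression aggregation, correlation tests, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fosnet as fn
from fosnet.io import ValidationError


def _counts(ctrl: np.ndarray, trt: np.ndarray) -> fn.FosCountTable:
    n = len(ctrl)
    regions = [f"R{i}" for i in range(n)]
    counts = pd.DataFrame(
        np.column_stack([ctrl, ctrl, trt, trt]),
        index=regions,
        columns=["c1", "c2", "t1", "t2"],
    )
    groups = {"c1": fn.CONTROL, "c2": fn.CONTROL, "t1": fn.TREATMENT, "t2": fn.TREATMENT}
    return fn.FosCountTable(counts=counts, group_of_subject=groups)


class TestFosLfc:
    def test_identical_group_means_zero(self):
        t = _counts(np.array([10, 20]), np.array([10, 20]))
        lfc = fn.fos_lfc(fn.normalize(t))
        assert np.allclose(lfc, 0.0)

    def test_tenfold_increase_near_one(self):
        t = _counts(np.array([1000, 5000]), np.array([10000, 50000]))
        lfc = fn.fos_lfc(fn.normalize(t))
        assert np.allclose(lfc, 1.0, atol=0.001)

    def test_toy_hand_arithmetic(self):
        t = _counts(np.array([9, 99]), np.array([99, 9]))
        lfc = fn.fos_lfc(fn.normalize(t))
        assert lfc["R0"] == pytest.approx(1.0)   # log10(100) - log10(10)
        assert lfc["R1"] == pytest.approx(-1.0)

    def test_excluded_regions_dropped(self):
        t = _counts(np.array([10, 20, 30]), np.array([40, 50, 60]))
        lfc = fn.fos_lfc(fn.normalize(t), excluded_regions=("R1",))
        assert list(lfc.index) == ["R0", "R2"]

    def test_single_group_rejected(self):
        counts = pd.DataFrame({"c1": [1, 2], "c2": [3, 4]}, index=["A", "B"])
        t = fn.FosCountTable(counts=counts, group_of_subject={"c1": fn.CONTROL, "c2": fn.CONTROL})
        with pytest.raises(ValidationError, match="both groups"):
            fn.fos_lfc(fn.normalize(t))


def _long(gene, exp, regions, values):
    return pd.DataFrame(
        {"gene_id": gene, "experiment_id": exp, "region_id": regions, "density": values}
    )


class TestAggregateExpression:
    regions = [f"R{i}" for i in range(5)]

    def test_single_experiment_zscored(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = fn.aggregate_expression(_long("g1", "e1", self.regions, v))
        expected = (v - v.mean()) / v.std()
        assert np.allclose(out.loc["g1", self.regions], expected)

    def test_identical_experiments_idempotent(self):
        v = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        expr = pd.concat(
            [_long("g1", "e1", self.regions, v), _long("g1", "e2", self.regions, v)]
        )
        one = fn.aggregate_expression(_long("g1", "e1", self.regions, v))
        two = fn.aggregate_expression(expr)
        assert np.allclose(one.loc["g1"], two.loc["g1"])

    def test_affine_experiments_average_to_common_zvector(self):
        v = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        expr = pd.concat(
            [_long("g1", "e1", self.regions, v), _long("g1", "e2", self.regions, 3 * v + 7)]
        )
        out = fn.aggregate_expression(expr)
        assert np.allclose(out.loc["g1"], (v - v.mean()) / v.std())

    def test_zero_variance_experiment_dropped(self):
        v = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        expr = pd.concat(
            [_long("g1", "e1", self.regions, v), _long("g1", "e2", self.regions, np.full(5, 3.0))]
        )
        out = fn.aggregate_expression(expr)
        assert np.allclose(out.loc["g1"], (v - v.mean()) / v.std())

    def test_gene_with_no_usable_experiment_excluded(self):
        expr = pd.concat(
            [
                _long("g1", "e1", self.regions, np.array([1.0, 4.0, 2.0, 8.0, 5.0])),
                _long("g2", "e2", self.regions, np.full(5, 9.0)),
            ]
        )
        out = fn.aggregate_expression(expr)
        assert list(out.index) == ["g1"]


class TestCorrelateGene:
    def test_proportional_vectors(self):
        lfc = pd.Series([0.1, 0.5, 0.9, 1.3], index=list("abcd"))
        r, p, n = fn.correlate_gene(2 * lfc + 1, lfc)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0) and n == 4

    def test_t_distribution_oracle_at_study_scale(self):
        """r = 0.23 over 174 regions lands at p ~ 2.3e-3, the two-sided
        t-test value at the |0.23| significance frontier."""
        n = 174
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=n), index=[f"R{i}" for i in range(n)])
        # build x with exact sample correlation 0.23 via orthogonalization
        e = pd.Series(rng.normal(size=n), index=y.index)
        yz = (y - y.mean()) / y.std(ddof=0)
        ez = e - e.mean()
        ez -= yz * (ez * yz).sum() / (yz * yz).sum()
        ez /= ez.std(ddof=0)
        target = 0.23
        x = target * yz + np.sqrt(1 - target**2) * ez
        r, p, _ = fn.correlate_gene(x, y)
        assert r == pytest.approx(0.23, abs=1e-12)
        t = 0.23 * np.sqrt((n - 2) / (1 - 0.23**2))
        assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-12)
        assert p == pytest.approx(2.27e-3, rel=0.01)

    def test_zero_variance_untestable(self):
        lfc = pd.Series([0.1, 0.5, 0.9], index=list("abc"))
        r, p, n = fn.correlate_gene(pd.Series([2.0, 2.0, 2.0], index=list("abc")), lfc)
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_shared_regions_rejected(self):
        lfc = pd.Series([0.1, 0.5], index=list("ab"))
        with pytest.raises(ValidationError, match=">=3"):
            fn.correlate_gene(pd.Series([1.0, 2.0], index=list("ab")), lfc)

    def test_null_p_values_uniform(self):
        """Independent vectors at the study's region count give uniform p
        (the t-test is calibrated); KS test at the 1% level."""
        n, reps = 174, 4000
        rng = np.random.default_rng(7)
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        # spot-check the vectorized oracle against the implementation
        ridx = pd.Index([f"R{i}" for i in range(n)])
        r0, p0, _ = fn.correlate_gene(pd.Series(x[0], index=ridx), pd.Series(y[0], index=ridx))
        assert p0 == pytest.approx(p[0], rel=1e-10)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_p(self):
        out = fn.bh_fdr(pd.Series({"g": 0.2}), 0.05)
        assert out.loc["g", "q"] == pytest.approx(0.2)

    def test_step_up_all_significant(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04], index=list("abcd"))
        out = fn.bh_fdr(p, 0.05)
        assert out["significant"].all()
        assert out.loc["d", "q"] == pytest.approx(0.04)

    def test_empty_input(self):
        out = fn.bh_fdr(pd.Series(dtype=float), 0.05)
        assert out.empty

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle(self, ps):
        """q_i = min over j >= rank(i) of m*p_(j)/j, capped at 1."""
        p = pd.Series(ps, index=[f"g{i}" for i in range(len(ps))])
        out = fn.bh_fdr(p, 0.05)
        m = len(ps)
        order = np.argsort(p.to_numpy(), kind="stable")
        sorted_p = p.to_numpy()[order]
        q_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
        q_oracle = np.empty(m)
        q_oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(out["q"].to_numpy(), q_oracle, atol=1e-12)
        # q monotone in sorted-p order, and q >= p
        assert (np.diff(np.minimum(q_sorted, 1.0)) >= -1e-12).all()
        assert (out["q"].to_numpy() >= out["p"].to_numpy() - 1e-12).all()


class TestRunScreen:
    def _setup(self, n_null, n_signal, seed=0, rho=0.4):
        cspec = fn.SyntheticCountSpec(
            n_regions=150, block_sizes=(50, 50, 50), n_subjects_per_group=5, seed=seed
        )
        table, _ = fn.generate_counts(cspec)
        cfg = fn.RunConfig()
        lfc = fn.fos_lfc(fn.normalize(table), cfg.excluded_regions)
        espec = fn.SyntheticExpressionSpec(
            n_null_genes=n_null, n_signal_genes=n_signal, signal_rho=rho, seed=seed + 1
        )
        expr, truth = fn.generate_expression(espec, lfc)
        return expr, table, truth, cfg

    def test_all_null_discovery_fraction_bounded(self):
        expr, table, _, cfg = self._setup(n_null=400, n_signal=0, seed=5)
        res = fn.run_screen(expr, table, cfg)
        assert res.table["significant"].mean() <= cfg.fdr_level + 0.02

    def test_planted_signals_recovered(self):
        expr, table, truth, cfg = self._setup(n_null=500, n_signal=50, seed=3)
        res = fn.run_screen(expr, table, cfg)
        sig = set(res.significant_genes())
        assert len(sig & truth.signal_gene_ids) / 50 > 0.5
        assert res.frontier > 0

    def test_output_sorted_by_abs_r(self):
        expr, table, _, cfg = self._setup(n_null=100, n_signal=10, seed=2)
        res = fn.run_screen(expr, table, cfg)
        absr = res.table["r"].abs().to_numpy()
        assert (np.diff(absr) <= 1e-12).all()

    def test_gene_order_invariance(self):
        expr, table, _, cfg = self._setup(n_null=50, n_signal=5, seed=8)
        shuffled = expr.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fn.run_screen(expr, table, cfg).table.sort_index()
        b = fn.run_screen(shuffled, table, cfg).table.sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_excluding_region_changes_bookkeeping_by_one(self):
        expr, table, _, cfg = self._setup(n_null=30, n_signal=0, seed=4)
        base = fn.run_screen(expr, table, cfg)
        cfg2 = cfg.with_overrides(excluded_regions=cfg.excluded_regions + ("R010",))
        fewer = fn.run_screen(expr, table, cfg2)
        assert base.n_regions_used - fewer.n_regions_used == 1
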