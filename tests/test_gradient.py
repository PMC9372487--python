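"""Gradient regressions, correlation tables, slope homogeneity, variation
partitioning."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isowue.errors import DomainError
from isowue.gradient import (
    compare_slopes,
    linear_regression,
    pearson_table,
    variation_partition,
)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        fit = linear_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        fit = linear_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert fit.slope == pytest.approx(0.6)
        assert fit.r2 == pytest.approx(0.36)

    def test_matches_closed_form(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        fit = linear_regression(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_degenerate_predictor(self):
        with pytest.raises(DomainError):
            linear_regression([1, 1, 1], [1, 2, 3])


class TestPearsonTable:
    def _frames(self, stats_vals, env_vals):
        n = len(next(iter(stats_vals.values())))
        ids = [f"S{i}" for i in range(n)]
        return (
            pd.DataFrame({"site_id": ids, **stats_vals}),
            pd.DataFrame({"site_id": ids, **env_vals}),
        )

    def test_self_and_negated_correlations(self):
        x = [1.0, 2.0, 4.0, 7.0]
        ss, env = self._frames(
            {"iWUE_mean": x, "iWUE_cv": [-v for v in x]},
            {"SM": x, "VPD": [0.1, 0.2, 0.3, 0.5], "SOC_TN": [9, 8, 7, 5]},
        )
        table = pearson_table(ss, env)
        assert table.loc["SM", ("iWUE_mean", "r")] == pytest.approx(1.0)
        assert table.loc["SM", ("iWUE_cv", "r")] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        ss, env = self._frames(
            {"iWUE_mean": [1.0, 2.0, 4.0], "iWUE_cv": [3.0, 2.0, 1.0]},
            {"SM": [1.0, 2.0, 3.0], "VPD": [1.0, 3.0, 2.0], "SOC_TN": [2.0, 2.5, 4.0]},
        )
        table = pearson_table(ss, env)
        # r between (1,2,3) and (1,2,4) = 0.98198 by direct formula
        assert table.loc["SM", ("iWUE_mean", "r")] == pytest.approx(0.98198, abs=1e-5)

    def test_constant_column_marked_nan(self):
        ss, env = self._frames(
            {"iWUE_mean": [1.0, 2.0, 3.0], "iWUE_cv": [1.0, 1.0, 1.0]},
            {"SM": [0.1, 0.2, 0.3], "VPD": [1, 2, 3], "SOC_TN": [4, 5, 6]},
        )
        table = pearson_table(ss, env)
        assert np.isnan(table.loc["SM", ("iWUE_cv", "r")])


class TestCompareSlopes:
    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            compare_slopes([([1, 2, 3], [1, 2, 3])])

    def test_distinct_slopes_detected(self, rng):
        x = np.linspace(0, 1, 60)
        g1 = (x, 1.0 * x + rng.normal(0, 0.01, 60))
        g2 = (x, 3.0 * x + rng.normal(0, 0.01, 60))
        _, p = compare_slopes([g1, g2])
        assert p < 1e-3

    def test_null_p_roughly_uniform(self, rng):
        from scipy import stats as sps

        ps = []
        x = np.linspace(0, 1, 30)
        for _ in range(200):
            g1 = (x, 2 * x + rng.normal(0, 1, 30))
            g2 = (x, 2 * x + rng.normal(0, 1, 30))
            ps.append(compare_slopes([g1, g2])[1])
        assert sps.kstest(ps, "uniform").statistic < 0.1


class TestVariationPartition:
    def _orthogonal_design(self, n=32):
        """Mutually orthogonal columns via a Hadamard-like construction."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        return Q  # orthonormal, zero-mean columns

    def test_pure_nutrient_response(self):
        Q = self._orthogonal_design()
        y = 2.0 * Q[:, 2]
        pf = variation_partition(y, Q[:, :2], Q[:, 2:], r2_kind="raw")
        assert pf.unique_nutrient == pytest.approx(1.0, abs=1e-10)
        assert pf.unique_water == pytest.approx(0.0, abs=1e-10)
        assert pf.shared == pytest.approx(0.0, abs=1e-10)

    def test_pure_water_response(self):
        Q = self._orthogonal_design()
        y = Q[:, 0].copy()
        pf = variation_partition(y, Q[:, :2], Q[:, 2:], r2_kind="raw")
        assert pf.unique_water == pytest.approx(1.0, abs=1e-10)
        assert pf.unexplained == pytest.approx(0.0, abs=1e-10)

    def test_shared_component_dominates_when_predictors_collinear(self, rng):
        common = rng.normal(size=200)
        Xw = np.column_stack(
            [common + rng.normal(0, 0.3, 200), rng.normal(size=200)]
        )
        Xn = (common + rng.normal(0, 0.3, 200)).reshape(-1, 1)
        y = common + rng.normal(0, 0.2, 200)
        pf = variation_partition(y, Xw, Xn, r2_kind="raw")
        assert pf.shared > pf.unique_water
        assert pf.shared > pf.unique_nutrient

    @given(st.integers(0, 1000))
    @settings(max_examples=40, derandomize=True)
    def test_raw_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        pf = variation_partition(
            y, rng.normal(size=(12, 2)), rng.normal(size=(12, 1)), r2_kind="raw"
        )
        total = pf.unique_water + pf.unique_nutrient + pf.shared + pf.unexplained
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_nested_r2_oracle(self, rng):
        """Fractions equal brute-force nested-model R2 differences computed
        with an independent least-squares route (normal equations)."""
        y = rng.normal(size=30)
        Xw = rng.normal(size=(30, 2))
        Xn = rng.normal(size=(30, 1))

        def r2_normal_eq(X):
            A = np.column_stack([np.ones(30), X])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            return 1 - resid @ resid / ((y - y.mean()) ** 2).sum()

        r2w, r2n = r2_normal_eq(Xw), r2_normal_eq(Xn)
        r2b = r2_normal_eq(np.column_stack([Xw, Xn]))
        pf = variation_partition(y, Xw, Xn, r2_kind="raw")
        assert pf.unique_water == pytest.approx(r2b - r2n, abs=1e-8)
        assert pf.unique_nutrient == pytest.approx(r2b - r2w, abs=1e-8)
        assert pf.shared == pytest.approx(r2w + r2n - r2b, abs=1e-8)

    def test_adjusted_fractions_reported_unclipped(self, rng):
        y = rng.normal(size=10)
        pf = variation_partition(
            y, rng.normal(size=(10, 2)), rng.normal(size=(10, 1)),
            r2_kind="adjusted",
        )
        assert dataclasses.asdict(pf)["r2_kind"] == "adjusted"
        # no clipping: with pure-noise y some fraction is usually negative
        vals = [pf.unique_water, pf.unique_nutrient, pf.shared]
        assert any(v < 0 for v in vals) or pf.unexplained > 1
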