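"""Community distribution statistics, ANOVA, Duncan's test, variance split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isowue.community import (
    distribution_characteristics,
    duncan_posthoc,
    one_way_anova,
    shapiro_wilk,
    site_distribution_table,
    within_among_partition,
)
from isowue.errors import DomainError, InapplicableTestError


class TestDistributionCharacteristics:
    def test_constant_sample(self):
        d = distribution_characteristics([10.0, 10.0, 10.0])
        assert (d.mean, d.sd, d.cv, d.range) == (10.0, 0.0, 0.0, 0.0)

    def test_one_to_five_frozen_values(self):
        """Bias-corrected conventions on 1..5, verified by hand formulas."""
        d = distribution_characteristics([1.0, 2.0, 3.0, 4.0, 5.0])
        assert d.mean == 3.0
        assert d.variance == pytest.approx(2.5)
        assert d.sd == pytest.approx(np.sqrt(2.5))
        assert d.cv == pytest.approx(100 * np.sqrt(2.5) / 3, abs=5e-3)
        assert d.range == 4.0
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.kurtosis == pytest.approx(-1.2)

    def test_mirrored_sample_has_zero_skewness(self, rng):
        x = rng.normal(5, 2, size=30)
        sym = np.concatenate([x, 2 * x.mean() - x])
        assert distribution_characteristics(sym).skewness == pytest.approx(
            0.0, abs=1e-10
        )

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=40),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_equivariance(self, xs, a, b):
        """mean/sd transform affinely; shape statistics are invariant
        under positive affine maps (when defined)."""
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            return
        d0 = distribution_characteristics(x)
        d1 = distribution_characteristics(a * x + b)
        assert d1.mean == pytest.approx(a * d0.mean + b, rel=1e-9, abs=1e-9)
        assert d1.sd == pytest.approx(a * d0.sd, rel=1e-9, abs=1e-9)
        assert d1.skewness == pytest.approx(d0.skewness, rel=1e-7, abs=1e-7)
        assert d1.kurtosis == pytest.approx(d0.kurtosis, rel=1e-7, abs=1e-7)

    def test_order_invariance(self, rng):
        x = rng.normal(size=25)
        a = distribution_characteristics(x)
        b = distribution_characteristics(x[rng.permutation(25)])
        assert a.mean == pytest.approx(b.mean)
        assert a.kurtosis == pytest.approx(b.kurtosis)

    def test_edge_cases(self):
        with pytest.raises(DomainError):
            distribution_characteristics([])
        d = distribution_characteristics([5.0])
        assert d.mean == 5.0 and np.isnan(d.sd) and "n1" in d.flags


class TestShapiroWilk:
    def test_too_small_or_constant(self):
        with pytest.raises(InapplicableTestError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(InapplicableTestError):
            shapiro_wilk([3.0] * 10)

    def test_null_p_uniformity(self, rng):
        ps = [shapiro_wilk(rng.normal(size=50))[1] for _ in range(200)]
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.1

    def test_gross_alternative_detected(self, rng):
        _, p = shapiro_wilk(rng.exponential(size=100))
        assert p < 0.01


class TestOneWayAnova:
    def test_toy_data_frozen(self):
        res = one_way_anova([(1, 2, 3), (4, 5, 6)])
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.F == pytest.approx(13.5)

    def test_two_groups_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_ss_additivity(self, rng):
        groups = [rng.normal(m, 1, rng.integers(5, 15)) for m in (0, 1, 3)]
        res = one_way_anova(groups)
        allx = np.concatenate(groups)
        ss_total = ((allx - allx.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(
            ss_total, rel=1e-10
        )

    def test_null_mean_F_near_one(self, rng):
        fs = [
            one_way_anova([rng.normal(size=40) for _ in range(4)]).F
            for _ in range(500)
        ]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.1)

    def test_degenerate(self):
        with pytest.raises(DomainError):
            one_way_anova([(1.0, 1.0), (1.0, 1.0)])


def _duncan_oracle(groups, labels, alpha=0.05):
    """Independent sequential-range oracle: builds the homogeneity matrix
    span-by-span (largest spans first) and marks separations directly."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df = sum(ns) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    order = np.argsort(-means)
    sm = means[order]
    sn = ns[order]
    homogeneous = np.zeros((k, k), dtype=bool)
    significant = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if homogeneous[i, j]:
                continue
            alpha_p = 1 - (1 - alpha) ** (span - 1)
            q = stats.studentized_range.ppf(1 - alpha_p, span, df)
            r_p = q * np.sqrt(mse / stats.hmean(sn[i : j + 1]))
            if sm[i] - sm[j] < r_p:
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        homogeneous[a, b] = True
            else:
                significant[i, j] = True
    return order, homogeneous, significant


class TestDuncan:
    def test_identical_groups_share_one_letter(self, rng):
        g = rng.normal(size=10)
        letters = duncan_posthoc([g, g + 1e-12, g - 1e-12])
        assert len(set(letters.values())) == 1

    def test_huge_separation_distinct_letters(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(40, 1, 10)  # ~20 pooled SDs apart
        letters = duncan_posthoc([a, b], labels=["lo", "hi"])
        assert set(letters["lo"]) & set(letters["hi"]) == set()

    def test_matches_independent_sequential_oracle(self, rng):
        groups = [
            rng.normal(0.0, 1.0, 12),
            rng.normal(0.4, 1.0, 12),
            rng.normal(3.0, 1.0, 12),
            rng.normal(3.3, 1.0, 12),
        ]
        labels = ["g1", "g2", "g3", "g4"]
        letters = duncan_posthoc(groups, labels=labels)
        order, homogeneous, significant = _duncan_oracle(groups, labels)
        # any pair declared significant by the oracle must share no letter,
        # and any homogeneous pair must share at least one
        for i in range(4):
            for j in range(i + 1, 4):
                li = set(letters[labels[order[i]]])
                lj = set(letters[labels[order[j]]])
                if significant[i, j] and not homogeneous[i, j]:
                    assert not (li & lj)
                if homogeneous[i, j]:
                    assert li & lj

    def test_two_group_case_agrees_with_pairwise_test(self, rng):
        """Duncan never separates two groups a plain two-group comparison
        at the same alpha would not separate."""
        for shift in (0.1, 0.5, 1.0, 2.0):
            a, b = rng.normal(0, 1, 10), rng.normal(shift, 1, 10)
            letters = duncan_posthoc([a, b], labels=["a", "b"])
            separated = not (set(letters["a"]) & set(letters["b"]))
            pairwise_p = one_way_anova([a, b]).p
            assert separated == (pairwise_p < 0.05)


class TestWithinAmong:
    def test_identical_sites_no_among_variance(self):
        recs = [("A", v) for v in (1, 2, 3)] + [("B", v) for v in (1, 2, 3)]
        w, a = within_among_partition(recs)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(100.0)

    def test_internally_constant_sites(self):
        recs = [("A", 1.0), ("A", 1.0), ("B", 5.0), ("B", 5.0)]
        w, a = within_among_partition(recs)
        assert w == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(100.0)

    def test_sums_to_100(self, rng):
        recs = [(f"S{i % 5}", v) for i, v in enumerate(rng.normal(size=100))]
        w, a = within_among_partition(recs)
        assert w + a == pytest.approx(100.0, abs=1e-9)

    def test_degenerate(self):
        with pytest.raises(DomainError):
            within_among_partition([("A", 1.0), ("A", 2.0)])
        with pytest.raises(DomainError):
            within_among_partition([("A", 1.0), ("B", 1.0)])


class TestSiteTable:
    def test_one_row_per_site(self, c3_derived):
        table = site_distribution_table(c3_derived)
        assert len(table) == c3_derived["site_id"].nunique()
        assert (table["n"] >= 1).all()
        ok = table["sd"].notna()
        assert np.allclose(
            table.loc[ok, "sd"] ** 2, table.loc[ok, "variance"], rtol=1e-10
        )
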