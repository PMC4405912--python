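import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from microtime import (
    OtuTimeSeries,
    RobustLoadNormalizer,
    fractional_normalize,
    reference_community,
    robust_normalize,
    robust_scaling_factor,
    select_abundant_otus,
    weighted_median,
)


def _series_from_fractions(frac: pd.DataFrame, scale: int = 10**6) -> OtuTimeSeries:
    counts = (frac * scale).round().astype(int)
    return OtuTimeSeries(counts=counts, fractions=None)


class TestSelectAbundantOtus:
    def test_prefix_covering_90_percent_of_medians(self):
        frac = pd.DataFrame(
            {"A": [0.5] * 3, "B": [0.3] * 3, "C": [0.15] * 3, "D": [0.05] * 3},
            index=[0, 1, 2],
        )
        series = OtuTimeSeries(counts=(frac * 100).astype(int), fractions=frac)
        assert set(select_abundant_otus(series, 0.9)) == {"A", "B", "C"}

    def test_full_coverage_keeps_all_nonzero_medians(self):
        frac = pd.DataFrame({"A": [0.7] * 3, "B": [0.3] * 3, "Z": [0.0] * 3})
        series = OtuTimeSeries(counts=(frac * 10).astype(int), fractions=frac)
        assert set(select_abundant_otus(series, 1.0)) == {"A", "B"}

    def test_single_otu(self):
        frac = pd.DataFrame({"A": [1.0, 1.0]})
        series = OtuTimeSeries(counts=(frac * 10).astype(int), fractions=frac)
        for cov in (0.1, 0.5, 1.0):
            assert list(select_abundant_otus(series, cov)) == ["A"]


class TestWeightedMedian:
    def test_lower_median_convention(self):
        assert weighted_median([1, 2, 10], [0.25, 0.25, 0.5]) == 2

    def test_all_weight_on_first(self):
        assert weighted_median([7, 1, 3], [1, 0, 0]) == 7

    def test_equal_weights_odd_n_is_ordinary_median(self, rng):
        for _ in range(20):
            v = rng.normal(size=7)
            assert weighted_median(v, np.ones(7)) == np.median(v)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            weighted_median([], [])

    def test_agrees_with_sort_scan_oracle(self, rng):
        def oracle(values, weights):
            order = np.argsort(values, kind="stable")
            v, w = np.asarray(values)[order], np.asarray(weights)[order]
            cum = np.cumsum(w) / np.sum(w)
            for vi, ci in zip(v, cum):
                if ci >= 0.5 - 1e-12:
                    return vi
            return v[-1]

        for _ in range(1000):
            n = rng.integers(1, 12)
            values = rng.integers(-5, 6, size=n).astype(float)
            weights = rng.random(n)
            weights[rng.random(n) < 0.3] = 0.0
            if weights.sum() == 0:
                weights[0] = 1.0
            assert weighted_median(values, weights) == oracle(values, weights)


class TestReferenceCommunity:
    def test_identical_days_recover_common_profile(self):
        frac = pd.DataFrame([[0.6, 0.3, 0.1]] * 4, columns=["A", "B", "C"])
        series = _series_from_fractions(frac)
        ref, weights = reference_community(series, 0)
        assert np.allclose(weights, 1.0)
        assert ref["A"] == pytest.approx(0.6)

    def test_two_days_lower_median_returns_target(self):
        frac = pd.DataFrame([[0.5, 0.5], [0.9, 0.1]], columns=["A", "B"])
        series = _series_from_fractions(frac)
        ref, weights = reference_community(series, 0, abundant_otus=pd.Index(["A", "B"]))
        assert weights.loc[0] == pytest.approx(1.0)
        assert weights.loc[1] < 1.0
        # with self-weight 1 dominating, the lower weighted median is the
        # target day's own value
        assert ref["A"] == pytest.approx(0.5)
        assert ref["B"] == pytest.approx(0.5)

    def test_self_weight_is_exactly_one(self, rng):
        frac = pd.DataFrame(rng.dirichlet(np.ones(4), size=5))
        series = _series_from_fractions(frac)
        _, weights = reference_community(series, 2)
        assert weights.loc[2] == pytest.approx(1.0)


class TestRobustScalingFactor:
    def test_outlier_resistant_fold_change(self):
        m, spread = robust_scaling_factor([10] * 5, [20, 20, 20, 20, 2])
        assert m == pytest.approx(2.0)
        assert spread == pytest.approx(0.0)

    def test_exact_threefold(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        m, spread = robust_scaling_factor(x, 3 * x)
        assert m == pytest.approx(3.0)
        assert spread == pytest.approx(0.0)

    def test_no_consensus_gives_large_spread(self):
        # log10 ratios are +1, -1 and 0: median residual is 1 -> discardable
        m, spread = robust_scaling_factor([1, 1, 1], [10, 0.1, 1])
        assert spread > 0.4

    def test_fewer_than_three_pairs_raises(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            robust_scaling_factor([1, 2, 0], [1, 0, 3])

    def test_median_breakdown_under_minority_perturbation(self, rng):
        # with <50% of OTUs arbitrarily perturbed, m equals the true fold
        # change exactly
        for _ in range(50):
            n = 11
            x = rng.uniform(0.01, 1, size=n)
            fold = rng.uniform(0.5, 2.0)
            y = fold * x
            k = rng.integers(1, (n - 1) // 2 + 1)
            idx = rng.choice(n, size=k, replace=False)
            y[idx] *= 10 ** rng.uniform(-2, 2, size=k)
            m, _ = robust_scaling_factor(x, y)
            assert m == pytest.approx(fold, rel=1e-9)


class TestRobustNormalize:
    def test_bloom_day_constant_otus_unchanged(self, bloom_series):
        """One OTU drops 90% on one day; the other four are flat in absolute
        terms.  Robust normalization leaves the flat OTUs exactly at their
        baseline fraction while sum-to-one normalization perturbs all four."""
        result = robust_normalize(bloom_series)
        rescaled_day4 = result.rescaled.loc[4]
        artifacts = (rescaled_day4[list("ABCD")] - 0.2).abs() > 1e-12
        assert artifacts.sum() == 0
        assert rescaled_day4["E"] == pytest.approx(0.02)
        # standard normalization perturbs all four flat OTUs
        std = fractional_normalize(bloom_series).fractions.loc[4]
        assert ((std[list("ABCD")] - 0.2).abs() > 1e-12).sum() == 4

    def test_bloom_day_load_recovered(self, bloom_series):
        result = robust_normalize(bloom_series)
        assert result.load.loc[4] == pytest.approx(41 / 50)
        assert np.allclose(result.load.loc[[0, 1, 2, 3]], 1.0)

    def test_constant_community_all_kept_m_one(self):
        counts = pd.DataFrame([[10, 20, 30, 40]] * 6, columns=list("ABCD"))
        result = robust_normalize(OtuTimeSeries(counts=counts))
        assert result.discarded_days == []
        assert np.allclose(result.load, 1.0)

    def test_day_violating_spread_rule_is_discarded(self, rng):
        frac = pd.DataFrame(
            np.tile(rng.dirichlet(np.ones(7) * 5), (8, 1)),
        )
        # day 7: scramble most OTUs by large independent factors
        row = frac.iloc[7].to_numpy() * 10 ** rng.uniform(-2, 2, size=7)
        frac.iloc[7] = row / row.sum()
        series = _series_from_fractions(frac, scale=10**7)
        result = robust_normalize(series)
        assert 7 in result.discarded_days

    def test_scale_equivariance_of_load(self):
        # doubling one day's absolute abundances halves nothing observable
        # in fractions, but halving the *other* OTUs' share shows up as a
        # proportional change in inferred load
        base = np.array([10.0, 10, 10, 10, 10])
        days = [base, base, base, base * np.array([1, 1, 1, 1, 3])]
        frac = pd.DataFrame([d / d.sum() for d in days])
        result = robust_normalize(_series_from_fractions(frac, scale=7 * 10**6))
        assert result.load.iloc[3] == pytest.approx(70 / 50, rel=1e-6)


class TestRobustLoadNormalizerEstimator:
    def test_sklearn_protocol(self):
        est = RobustLoadNormalizer(coverage=0.8, discard_threshold=0.3)
        assert est.get_params() == {"coverage": 0.8, "discard_threshold": 0.3}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_transform_matches_function(self, bloom_series):
        series = fractional_normalize(bloom_series)
        est = RobustLoadNormalizer().fit(series.fractions)
        rescaled = est.transform(series.fractions)
        result = robust_normalize(bloom_series)
        pd.testing.assert_frame_equal(
            rescaled.loc[result.rescaled.index], result.rescaled
        )

    def test_transform_new_day_against_fitted_reference(self, bloom_series):
        series = fractional_normalize(bloom_series)
        est = RobustLoadNormalizer().fit(series.fractions.iloc[:4])
        new = series.fractions.iloc[[4]]
        out = est.transform(new)
        assert np.allclose(out.loc[4, list("ABCD")], 0.2)
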