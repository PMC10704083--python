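"""Tests for outlier filtering, aggregation and the from-scratch KS test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gasmas.inversion import GasEstimate
from gasmas.stats_qc import (
    _asymptotic_p_value,
    _ks_statistic_numerator,
    aggregate_replicates,
    compare_configurations,
    concentration_boxes,
    flag_outliers,
    holm_adjust,
    ks_two_sample,
)


def make_estimate(pathlength, config_id="cfg", replicate=1, o2=0.21, valid=True):
    return GasEstimate(
        config_id=config_id,
        replicate=replicate,
        o2_nominal=0.21,
        pathlength=pathlength,
        o2_fraction=o2,
        snr_764=10.0,
        snr_820=10.0,
        valid=valid,
    )


def brute_force_permutation_p(x, y):
    """Oracle: exhaustive enumeration of all label assignments."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    h_obs = _ks_statistic_numerator(np.asarray(x, float), np.asarray(y, float))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        hits += _ks_statistic_numerator(pooled[mask], pooled[~mask]) >= h_obs
        total += 1
    return hits / total


class TestFlagOutliers:
    def test_protocol_rule_on_constructed_set(self):
        estimates = [make_estimate(v, replicate=i)
                     for i, v in enumerate([0.0, 0.10, 0.229, 0.230, 0.231])]
        flagged = flag_outliers(estimates)
        assert [e.outlier for e in flagged] == [True, False, False, False, True]

    def test_idempotent_and_order_independent(self):
        values = [0.0, 0.05, 0.3, 0.15, 0.231]
        estimates = [make_estimate(v, replicate=i) for i, v in enumerate(values)]
        once = flag_outliers(estimates)
        twice = flag_outliers(once)
        assert once == twice
        reversed_flags = flag_outliers(estimates[::-1])
        assert [e.outlier for e in reversed_flags] == [e.outlier for e in once][::-1]

    def test_invalid_estimates_are_outliers(self):
        flagged = flag_outliers([make_estimate(0.1, valid=False)])
        assert flagged[0].outlier

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([], low=0.3, high=0.2)


class TestAggregateReplicates:
    def test_identical_values(self):
        estimates = [make_estimate(0.1, replicate=i) for i in range(21)]
        summary = aggregate_replicates(flag_outliers(estimates))
        assert summary.mean_pathlength == pytest.approx(0.1)
        assert summary.sd_pathlength == pytest.approx(0.0, abs=1e-15)
        assert summary.n_total == 21
        assert summary.n_outliers == 0

    def test_outliers_excluded_from_mean(self):
        estimates = [make_estimate(v, replicate=i)
                     for i, v in enumerate([0.1, 0.1, 0.25])]
        summary = aggregate_replicates(flag_outliers(estimates))
        assert summary.mean_pathlength == pytest.approx(0.1)
        assert summary.n_outliers == 1

    def test_all_outliers_yields_empty_summary(self):
        estimates = [make_estimate(0.0, replicate=i) for i in range(3)]
        summary = aggregate_replicates(flag_outliers(estimates))
        assert summary.mean_pathlength is None
        assert summary.n_outliers == 3

    def test_mean_within_range_of_included(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.02, 0.2, size=21)
        estimates = [make_estimate(v, replicate=i) for i, v in enumerate(values)]
        summary = aggregate_replicates(flag_outliers(estimates))
        assert values.min() <= summary.mean_pathlength <= values.max()

    def test_mixed_config_ids_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates(
                [make_estimate(0.1, config_id="a"), make_estimate(0.1, config_id="b")]
            )


class TestKsTwoSample:
    def test_identical_samples(self):
        result = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="asymp")
        assert result.d_statistic == 0.0
        assert result.p_value == 1.0
        assert result.comparable

    def test_disjoint_supports(self):
        result = ks_two_sample([1.0, 2.0], [3.0, 4.0])
        assert result.d_statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n1, n2 = rng.integers(1, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            result = ks_two_sample(x, y)  # auto -> exact for these sizes
            assert result.method == "exact"
            assert result.p_value == pytest.approx(
                brute_force_permutation_p(x, y), abs=1e-12
            )

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            exact = ks_two_sample(x, y, method="exact").p_value
            asymp = ks_two_sample(x, y, method="asymp").p_value
            # Stephens-corrected series is a decent but not sharp small-n
            # approximation; at n=12 the deviation stays modest
            assert asymp == pytest.approx(exact, abs=0.15)

    def test_asymptotic_series_value(self):
        # hand-evaluated single-term check: large lambda -> ~2 exp(-2 lam^2)
        d, n1, n2 = 0.8, 10, 10
        ne = 50 / 10  # n1*n2/(n1+n2)
        lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
        assert _asymptotic_p_value(d, n1, n2) == pytest.approx(
            2 * math.exp(-2 * lam**2), rel=1e-6
        )

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=10, unique=True),
        st.lists(st.floats(-50, 50), min_size=2, max_size=10, unique=True),
    )
    @settings(max_examples=40, deadline=None)
    def test_d_invariant_under_monotone_transform(self, x, y):
        d_raw = ks_two_sample(x, y).d_statistic
        fx = [math.atan(0.1 * v) for v in x]
        fy = [math.atan(0.1 * v) for v in y]
        assert ks_two_sample(fx, fy).d_statistic == pytest.approx(d_raw, abs=1e-12)

    def test_ties_handled_by_asymptotic_fallback(self):
        result = ks_two_sample([1.0, 1.0, 2.0], [1.0, 3.0], method="auto")
        assert result.method == "asymp"
        with pytest.raises(ValueError, match="tie"):
            ks_two_sample([1.0, 1.0], [1.0], method="exact")


class TestCompareConfigurations:
    def test_self_comparison_p_one(self):
        samples = {"a": [0.1, 0.11, 0.12]}
        [(_, _, result)] = compare_configurations(samples, [("a", "a")])
        assert result.p_value == 1.0
        assert result.comparable

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            compare_configurations({"a": [1.0]}, [("a", "b")])

    def test_identical_truth_groups_usually_comparable(self):
        rng = np.random.default_rng(9)
        n_pass = 0
        for _ in range(20):
            x = 0.1 + 1e-4 * rng.normal(size=21)
            y = 0.1 + 1e-4 * rng.normal(size=21)
            n_pass += ks_two_sample(x, y, method="asymp").comparable
        assert n_pass >= 18  # >= 90% of seeded draws

    def test_distinct_truths_not_comparable(self):
        rng = np.random.default_rng(10)
        x = 0.05 + 1e-4 * rng.normal(size=21)
        y = 0.15 + 1e-4 * rng.normal(size=21)
        assert not ks_two_sample(x, y, method="asymp").comparable


class TestHolmAdjust:
    def test_monotone_and_bounded(self):
        adjusted = holm_adjust([0.01, 0.04, 0.03, 0.5])
        assert all(0 <= p <= 1 for p in adjusted)
        assert adjusted[0] == pytest.approx(0.04)
        assert adjusted[3] == pytest.approx(0.5)


class TestConcentrationBoxes:
    def test_single_value_degenerate_box(self):
        [box] = concentration_boxes([make_estimate(0.1, o2=0.30)])
        assert box.median == box.q1 == box.q3 == 30.0
        assert box.whisker_low == box.whisker_high == 30.0
        assert box.outlier_values == ()

    def test_type7_quantile_convention(self):
        estimates = [
            make_estimate(0.1, replicate=i, o2=v / 100.0)
            for i, v in enumerate(range(1, 101))
        ]
        [box] = concentration_boxes(estimates)
        assert box.median == pytest.approx(50.5)
        assert box.q1 == pytest.approx(25.75)
        assert box.q3 == pytest.approx(75.25)

    def test_far_points_listed_as_fliers(self):
        values = [0.20, 0.21, 0.22, 0.23, 0.24, 0.80]
        estimates = [make_estimate(0.1, replicate=i, o2=v)
                     for i, v in enumerate(values)]
        [box] = concentration_boxes(estimates)
        assert box.outlier_values == (80.0,)
        assert box.whisker_high == 24.0
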