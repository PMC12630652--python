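"""Stratified exact-binomial estimator: equivalences, monotonicity, arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import beta

from cafomap import (
    Stratum,
    estimate_total_facilities,
    estimate_unobserved_images,
    images_per_facility_ratio,
    stratum_weights,
    waller_interval,
)
from cafomap.completeness import estimate_population, round_half_away


def clopper_pearson(x, n, alpha=0.05):
    lo = 0.0 if x == 0 else beta.ppf(alpha / 2, x, n - x + 1)
    hi = 1.0 if x == n else beta.ppf(1 - alpha / 2, x + 1, n - x)
    return lo, hi


def s(x, n, N=None, cat="no_detection", sid="s0"):
    return Stratum(sid, cat, total=N if N is not None else n * 10, labeled=n, positives=x)


class TestWallerInterval:
    @pytest.mark.parametrize("n", [5, 17, 60, 400])
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.10])
    def test_single_stratum_is_clopper_pearson(self, n, alpha):
        """With one stratum R = 1 and the interval must equal the exact
        binomial interval computed independently from beta quantiles."""
        for x in range(0, n + 1, max(1, n // 9)):
            iv = waller_interval([s(x, n)], alpha=alpha)
            lo, hi = clopper_pearson(x, n, alpha)
            assert iv.r == pytest.approx(1.0, abs=1e-12)
            assert iv.lb == pytest.approx(lo, abs=1e-10)
            assert iv.ub == pytest.approx(hi, abs=1e-10)

    def test_all_zero_positives_is_one_sided(self):
        strata = [s(0, 500, sid=f"s{i}") for i in range(4)]
        iv = waller_interval(strata)
        assert iv.p_hat == 0.0
        assert iv.lb == 0.0
        assert iv.ub > 0.0

    def test_two_equal_strata_contain_pooled_point_estimate(self):
        """For two equal-size strata the stratified interval must contain
        the pooled-sample proportion across a grid of outcomes."""
        n = 120
        for x1 in (0, 1, 3, 10):
            for x2 in (0, 2, 7):
                iv = waller_interval(
                    [s(x1, n, sid="a"), s(x2, n, N=n * 5, sid="b")]
                )
                pooled = (x1 + x2) / (2 * n)
                assert iv.lb <= pooled + 1e-12
                assert iv.ub >= pooled - 1e-12

    def test_upper_bound_monotone_in_positives(self):
        n = 200
        ubs = [
            waller_interval([s(x, n, sid="a"), s(1, n, sid="b")]).ub
            for x in range(0, 8)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(ubs, ubs[1:]))

    def test_point_estimate_linear_in_positives(self):
        n = 100
        p0 = waller_interval([s(0, n, sid="a"), s(0, n, sid="b")]).p_hat
        p1 = waller_interval([s(2, n, sid="a"), s(0, n, sid="b")]).p_hat
        p2 = waller_interval([s(4, n, sid="a"), s(0, n, sid="b")]).p_hat
        assert p1 - p0 == pytest.approx(p2 - p1, abs=1e-14)

    def test_zero_labeled_stratum_raises_with_name(self):
        with pytest.raises(ValueError, match="empty_one"):
            waller_interval(
                [s(0, 10, sid="ok"),
                 Stratum("empty_one", "no_detection", total=5, labeled=0, positives=0)]
            )

    @pytest.mark.parametrize("p", [0.0001, 0.001, 0.01])
    def test_upper_bound_coverage_conservative_for_rare_events(self, p):
        """The upper bound — the side driving the completeness CI — covers
        the true rare-event proportion at well above the nominal one-sided
        rate (97.5%) in a 26-stratum design.  (The two-sided statement
        does not hold at rare rates: the adjustment factor shrinks the
        lower bound toward the point estimate.)"""
        rng = np.random.default_rng(515)
        n_i = rng.integers(200, 2_000, size=26)
        reps = 400
        draws = rng.binomial(n_i[None, :].repeat(reps, axis=0), p)
        covered = 0
        for rep in range(reps):
            strata = [
                Stratum(f"s{i}", "no_detection", int(10 * n_i[i]),
                        int(n_i[i]), int(draws[rep, i]))
                for i in range(26)
            ]
            if p <= waller_interval(strata).ub:
                covered += 1
        assert covered / reps >= 0.975

    def test_interval_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            strata = [
                s(int(rng.integers(0, 5)), int(rng.integers(20, 500)), sid=f"s{i}")
                for i in range(int(rng.integers(1, 6)))
            ]
            iv = waller_interval(strata)
            assert 0.0 <= iv.lb <= iv.p_hat <= iv.ub <= 1.0


class TestWeights:
    def test_single_stratum(self):
        assert stratum_weights([s(0, 10)]) == pytest.approx([1.0])

    def test_proportional_to_totals(self):
        w = stratum_weights([s(0, 10, N=100, sid="a"), s(0, 10, N=300, sid="b")])
        assert w == pytest.approx([0.25, 0.75])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=26))
    def test_weights_sum_to_one(self, totals):
        strata = [s(0, 1, N=N, sid=f"s{i}") for i, N in enumerate(totals)]
        assert stratum_weights(strata).sum() == pytest.approx(1.0)

    def test_mixed_categories_rejected(self):
        with pytest.raises(ValueError):
            stratum_weights([s(0, 5, cat="no_detection", sid="a"),
                             s(0, 5, cat="low_confidence", sid="b")])


class TestCountsAndRatios:
    def test_zero_proportion_gives_zero_images(self):
        iv = waller_interval([s(0, 100)])
        assert estimate_unobserved_images(iv, 10_000)[0] == 0

    @pytest.mark.parametrize(
        "p,U,expected", [(0.0013, 393_355, 511), (1.0, 10, 10), (0.5, 3, 2)]
    )
    def test_image_scaling_and_rounding(self, p, U, expected):
        assert round_half_away(p * U) == expected

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(1.5) == 2
        assert round_half_away(2.5) == 3
        assert round_half_away(-0.5) == -1

    def test_shared_images_ratio(self):
        # ten facilities on the same two images: 0.2 images per facility
        assert images_per_facility_ratio(2, 10) == pytest.approx(0.2)
        assert images_per_facility_ratio(3, 1) == pytest.approx(3.0)

    def test_ratio_requires_facilities(self):
        with pytest.raises(ValueError):
            images_per_facility_ratio(5, 0)


class TestPopulationEstimate:
    def test_no_unobserved_images_means_complete(self):
        est = estimate_total_facilities(100, 0, 0, 1.44)
        assert est.completeness_point_pct == 100
        assert est.total_facilities_point == 100

    def test_total_never_below_observed(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            est = estimate_total_facilities(
                int(rng.integers(1, 5000)),
                int(rng.integers(0, 300)),
                int(rng.integers(300, 900)),
                float(rng.uniform(0.2, 3.0)),
            )
            assert est.total_facilities_point >= est.observed_facilities
            assert est.total_facilities_ub >= est.total_facilities_point
            assert est.completeness_point_pct <= 100

    def test_end_to_end_report_structure(self):
        strata = [
            s(0, 200, N=2000, cat="no_detection", sid="no_detection/1"),
            s(1, 200, N=2000, cat="no_detection", sid="no_detection/2"),
            s(2, 100, N=500, cat="low_confidence", sid="low_confidence/1"),
        ]
        report = estimate_population(strata, observed_facilities=150,
                                     images_per_facility=1.2)
        assert set(report["categories"]) == {"no_detection", "low_confidence"}
        est = report["estimate"]
        assert est["total_facilities_ub"] >= est["total_facilities_point"]
        lo, hi = est["completeness_ci_pct"]
        assert lo <= hi == est["completeness_point_pct"]
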