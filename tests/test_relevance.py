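"""s0 derivation, adjusted F, relevance score, classification boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseresp.fitting import FitBundle
from doseresp.models import LogisticParams, MeanFit
from doseresp.relevance import (
    Boundary,
    CurveStatistics,
    NotRegulatedRule,
    adjusted_f,
    classify_curve,
    compute_s0,
    hyperbolic_boundary_test,
    relevance_score,
)
from doseresp.significance import p_value

# quadrature oracle (hand-written density + quad), frozen before the build:
# -log10 of the shifted upper tail at f_adj = 2.5, n = 10
RELEVANCE_ORACLE_2P5_N10 = 0.7916802798201276


def make_fit(intercept=1.0, rmse=0.05, n=10):
    return FitBundle(
        curve_id="c", params=LogisticParams(6.5, 1.0, 1.0, 0.5),
        sse_m1=0.01, mean_fit=MeanFit(intercept), sse_m0=rmse**2 * n,
        rmse_m0=rmse, n=n, converged=True, n_starts_used=3,
        x_min=-9.0, x_max=-4.0,
    )


def make_stats(f=1.0, cfc=0.0, relevance=0.0, p=0.5, n=10):
    return CurveStatistics(
        curve_id="c", f=f, dfd=5.94, p=p, cfc=cfc, f_adj=f,
        relevance=relevance, n=n,
    )


class TestComputeS0:
    def test_one_percent_alpha_with_seventeen_points(self):
        assert compute_s0(0.01, 0.3, 17) == pytest.approx(0.13, abs=0.005)

    def test_five_percent_alpha_with_ten_points(self):
        assert compute_s0(0.05, 0.45, 10) == pytest.approx(0.214, abs=0.005)

    def test_zero_fold_change_asymptote(self):
        assert compute_s0(0.2, 0.0, 10) == 0.0

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            compute_s0(0.0, 0.3, 10)
        with pytest.raises(ValueError):
            compute_s0(1.0, 0.3, 10)


class TestAdjustedF:
    def test_s0_zero_reduces_to_f(self):
        assert adjusted_f(4.0, 0.7, 0.0) == 4.0
        assert adjusted_f(4.0, -0.7, 0.0) == 4.0

    def test_arithmetic(self):
        expected = 1.0 / (0.5 + 0.214 / 0.45) ** 2
        assert adjusted_f(4.0, 0.45, 0.214) == pytest.approx(expected, rel=1e-9)

    def test_infinite_f_limit(self):
        assert adjusted_f(np.inf, 0.45, 0.214) == pytest.approx((0.45 / 0.214) ** 2)

    def test_zero_conventions(self):
        assert adjusted_f(0.0, 0.5, 0.2) == 0.0
        assert adjusted_f(3.0, 0.0, 0.2) == 0.0

    def test_symmetric_in_sign_of_cfc(self):
        assert adjusted_f(3.0, -0.6, 0.2) == adjusted_f(3.0, 0.6, 0.2)

    @given(f=st.floats(0.01, 1e4), cfc=st.floats(0.01, 5.0), s0=st.floats(1e-6, 2.0))
    @settings(max_examples=300, deadline=None)
    def test_never_exceeds_f(self, f, cfc, s0):
        assert adjusted_f(f, cfc, s0) <= f


class TestRelevanceScore:
    def test_zero_tail_probability_one(self):
        assert relevance_score(0.0, 10) == 0.0

    def test_s0_zero_equals_minus_log10_p(self):
        for f in (0.5, 2.0, 7.0):
            assert relevance_score(adjusted_f(f, 0.8, 0.0), 10) == pytest.approx(
                -np.log10(p_value(f, 10)), rel=1e-12
            )

    def test_quadrature_oracle(self):
        assert relevance_score(2.5, 10) == pytest.approx(
            RELEVANCE_ORACLE_2P5_N10, rel=1e-7
        )

    def test_monotone_in_f_adj(self):
        scores = [relevance_score(f, 10) for f in np.linspace(0, 30, 500)]
        assert np.all(np.diff(scores) >= 0)

    def test_penalty_monotone_in_effect_size(self):
        """At fixed F, relevance never decreases as |cfc| grows."""
        s0 = compute_s0(0.05, 0.3, 10)
        for f in (1.0, 4.0, 20.0):
            scores = [
                relevance_score(adjusted_f(f, c, s0), 10)
                for c in np.linspace(0.01, 3.0, 200)
            ]
            assert np.all(np.diff(scores) >= -1e-12)


class TestClassification:
    def test_significant_down(self):
        b = Boundary(0.05, 0.3)
        st_ = make_stats(f=50.0, cfc=-1.0, relevance=5.0)
        assert classify_curve(st_, make_fit(), b) == "down"

    def test_significant_up(self):
        b = Boundary(0.05, 0.3)
        st_ = make_stats(f=50.0, cfc=0.8, relevance=5.0)
        assert classify_curve(st_, make_fit(), b) == "up"

    def test_flat_quiet_curve_is_not_regulated(self):
        b = Boundary(0.05, 0.3)
        st_ = make_stats(f=0.1, cfc=0.01, relevance=0.05)
        assert classify_curve(st_, make_fit(intercept=1.0, rmse=0.05), b) == "not"

    def test_noisy_flat_curve_is_unclear(self):
        b = Boundary(0.05, 0.3)
        st_ = make_stats(f=0.1, cfc=0.01, relevance=0.05)
        assert classify_curve(st_, make_fit(intercept=1.0, rmse=0.3), b) == "unclear"

    def test_shifted_intercept_is_unclear(self):
        b = Boundary(0.05, 0.3)
        st_ = make_stats(relevance=0.05)
        # |log2(1.5)| = 0.58 > fc_lim/2 = 0.15
        assert classify_curve(st_, make_fit(intercept=1.5, rmse=0.05), b) == "unclear"

    def test_optional_p_criterion(self):
        b = Boundary(0.05, 0.3)
        rule = NotRegulatedRule(not_p_min=0.5)
        st_ = make_stats(relevance=0.05, p=0.2)
        assert classify_curve(st_, make_fit(), b, rule) == "unclear"
        st_ = make_stats(relevance=0.05, p=0.9)
        assert classify_curve(st_, make_fit(), b, rule) == "not"


class TestHyperbolicBoundary:
    def test_small_effect_size_never_regulated(self):
        b = Boundary(0.05, 0.45)
        for f in (1.0, 100.0, 1e6, np.inf):
            assert not hyperbolic_boundary_test(f, 0.44, b, 10)
            assert not hyperbolic_boundary_test(f, -0.44, b, 10)

    def test_weak_f_never_regulated(self):
        b = Boundary(0.05, 0.3)
        for cfc in (1.0, 10.0, 100.0):
            assert not hyperbolic_boundary_test(0.5, cfc, b, 10)

    def test_strong_f_above_asymptote_regulated(self):
        b = Boundary(0.05, 0.3)
        assert hyperbolic_boundary_test(1e5, 0.6, b, 10)

    @given(
        f=st.floats(0.0, 1e4),
        cfc=st.floats(-4.0, 4.0),
        n=st.integers(6, 24),
    )
    @settings(max_examples=400, deadline=None)
    def test_equivalent_to_relevance_threshold(self, f, cfc, n):
        """The explicit boundary form and the classify threshold agree."""
        b = Boundary(0.05, 0.3)
        s0 = b.s0_for_n(n)
        score = relevance_score(adjusted_f(f, cfc, s0), n)
        via_threshold = score >= b.relevance_threshold
        assert hyperbolic_boundary_test(f, cfc, b, n) == via_threshold
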