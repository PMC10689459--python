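"""Multi-start bounded fitting: start grid, objectives, global-minimum quality."""

import numpy as np
import pytest

from doseresp._batch import batch_fit
from doseresp.fitting import (
    FitOptions,
    InsufficientPointsError,
    build_start_grid,
    fit_curves,
    fit_loglogistic,
    negative_log_likelihood,
)
from doseresp.models import CurveData, LogisticParams, loglogistic_eval

X10 = np.linspace(-9.0, -4.0, 10)


def make_curve(params, sigma=0.0, rng=None, x=X10, cid="c"):
    y = loglogistic_eval(params, x)
    if sigma:
        y = y + rng.normal(0.0, sigma, len(x))
    return CurveData(cid, x, y)


class TestStartGrid:
    def test_grid_cardinality(self):
        curve = make_curve(LogisticParams(6.5, 1.0, 1.0, 0.3))
        starts = build_start_grid(curve)
        # 7 pEC50 positions x 3 slopes x 2 orientations
        assert len(starts) == 42

    def test_constant_data_keeps_flat_starts(self):
        curve = CurveData("c", X10, np.ones(10))
        starts = build_start_grid(curve)
        assert any(s.front == s.back for s in starts)
        # percentiles of constant y collapse -> orientation dedup halves the grid
        assert len(starts) == 21

    def test_single_point_curve_refused_downstream(self):
        curve = CurveData("c", [-7.0], [1.0])
        assert len(build_start_grid(curve)) >= 1
        with pytest.raises(InsufficientPointsError):
            fit_loglogistic(curve)


class TestNegLogLikelihood:
    def test_zero_residuals_unit_variance(self):
        p = LogisticParams(6.5, 1.0, 1.0, 0.3)
        curve = make_curve(p)
        n = curve.n
        assert negative_log_likelihood(p, 1.0, curve) == pytest.approx(
            n / 2 * np.log(2 * np.pi)
        )

    def test_hand_arithmetic(self):
        # SSE=2, sigma2=1, n=4 -> 2 ln(2 pi) + 1
        x = np.array([-9.0, -8.0, -7.0, -6.0])
        p = LogisticParams(20.0, 1.0, 1.0, 1.0)  # flat at 1
        y = 1.0 + np.array([1.0, -1.0, 1.0, -1.0]) / np.sqrt(2)
        curve = CurveData("c", x, y)
        assert negative_log_likelihood(p, 1.0, curve) == pytest.approx(
            2 * np.log(2 * np.pi) + 1.0
        )

    def test_profiled_sigma2_is_sse_over_n(self):
        rng = np.random.default_rng(5)
        p = LogisticParams(6.5, 1.0, 1.0, 0.3)
        curve = make_curve(p, sigma=0.1, rng=rng)
        resid = curve.y - loglogistic_eval(p, curve.x)
        sse = float((resid**2).sum())
        grid = np.linspace(0.2, 5.0, 400) * sse / curve.n
        vals = [negative_log_likelihood(p, s2, curve) for s2 in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(sse / curve.n, rel=2e-2)

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(
                LogisticParams(6.5, 1, 1, 1), 0.0, make_curve(LogisticParams(6.5, 1, 1, 1))
            )


class TestFitLoglogistic:
    def test_noise_free_recovery(self):
        truth = LogisticParams(7.0, 1.0, 1.0, 0.3)
        fb = fit_loglogistic(make_curve(truth))
        assert fb.params.pec50 == pytest.approx(7.0, abs=1e-3)
        assert fb.params.slope == pytest.approx(1.0, abs=1e-3)
        assert fb.params.front == pytest.approx(1.0, abs=1e-3)
        assert fb.params.back == pytest.approx(0.3, abs=1e-3)
        assert fb.sse_m1 == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_matches_mean_model(self):
        curve = CurveData("c", X10, np.full(10, 0.7))
        fb = fit_loglogistic(curve)
        assert fb.sse_m1 <= fb.sse_m0 + 1e-12
        assert fb.mean_fit.intercept == pytest.approx(0.7)

    def test_orientation_of_decreasing_curve(self):
        rng = np.random.default_rng(2)
        fb = fit_loglogistic(make_curve(LogisticParams(6.5, 1.0, 1.0, 0.4), 0.02, rng))
        assert fb.params.front > fb.params.back

    def test_sse_never_exceeds_mean_model(self):
        rng = np.random.default_rng(3)
        for i in range(20):
            curve = CurveData("c", X10, 1 + rng.normal(0, 0.1, 10))
            fb = fit_loglogistic(curve)
            assert fb.sse_m1 <= fb.sse_m0 * (1 + 1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        curve = make_curve(LogisticParams(6.0, 1.5, 1.0, 0.5), 0.05, rng)
        fb1 = fit_loglogistic(curve)
        fb2 = fit_loglogistic(curve)
        assert fb1.params == fb2.params
        assert fb1.sse_m1 == fb2.sse_m1

    def test_mle_agrees_with_ols_argmin(self):
        rng = np.random.default_rng(6)
        curve = make_curve(LogisticParams(6.5, 1.0, 1.0, 0.4), 0.05, rng)
        ols = fit_loglogistic(curve, objective="OLS")
        mle = fit_loglogistic(curve, objective="MLE")
        # profiled-likelihood argmin over theta equals the OLS argmin
        assert mle.sse_m1 == pytest.approx(ols.sse_m1, rel=1e-6)
        assert mle.sigma2_mle == pytest.approx(ols.sse_m1 / curve.n, rel=1e-6)


class TestBatchEngine:
    def test_batch_matches_percurve_scipy(self):
        """The vectorised engine must reach the same optima as the scipy path."""
        rng = np.random.default_rng(7)
        curves = []
        for i in range(40):
            truth = LogisticParams(rng.uniform(5, 8), rng.uniform(0.5, 2), 1.0, rng.uniform(0.3, 2.0))
            curves.append(make_curve(truth, 0.05, rng, cid=f"c{i}"))
        Y = np.stack([c.y for c in curves])
        _, sse_batch = batch_fit(X10, Y)
        for i, c in enumerate(curves):
            fb = fit_loglogistic(c)
            # same basin: neither engine beats the other beyond optimizer slack
            assert sse_batch[i] <= fb.sse_m1 * (1 + 1e-3) + 1e-12
            assert fb.sse_m1 <= sse_batch[i] * (1 + 1e-3) + 1e-12

    def test_global_fit_property(self):
        """Fitted SSE never exceeds the SSE at the true parameters."""
        rng = np.random.default_rng(8)
        n_curves = 500
        pec = rng.uniform(5.5, 7.5, n_curves)
        Ytrue = np.stack(
            [loglogistic_eval(LogisticParams(p, 1.0, 1.0, 0.5), X10) for p in pec]
        )
        Y = Ytrue + rng.normal(0, 0.05, Ytrue.shape)
        _, sse = batch_fit(X10, Y)
        sse_truth = ((Y - Ytrue) ** 2).sum(1)
        assert np.all(sse <= sse_truth * (1 + 1e-6))

    def test_fit_curves_skips_short_curves(self):
        good = make_curve(LogisticParams(6.5, 1, 1, 0.4), cid="good")
        short = CurveData("short", [-9.0, -8.0], [1.0, 0.9])
        fits, skipped = fit_curves([good, short])
        assert [f.curve_id for f in fits] == ["good"]
        assert skipped[0][0] == "short"

    def test_fit_curves_deterministic_across_grouping(self):
        rng = np.random.default_rng(9)
        curves = [
            make_curve(LogisticParams(6.5, 1, 1, 0.5), 0.05, rng, cid=f"c{i}")
            for i in range(12)
        ]
        fits_a, _ = fit_curves(curves)
        fits_b, _ = fit_curves(curves)
        for a, b in zip(fits_a, fits_b):
            assert a.params == b.params
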