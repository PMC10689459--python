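"""Bounded multi-start fitting of the log-logistic model.

The fit problem is non-convex: a steep curve can model a step between
any pair of adjacent doses, so local optimisation from a single start
frequently stalls in a side minimum.  The strategy here is

1. build a deterministic grid of start candidates across the dose
   range (:func:`build_start_grid`);
2. cheaply rank (pEC50, slope) candidates with a variable-projection
   screen in which the conditionally optimal plateaus are solved in
   closed form;
3. run a bounded local optimisation from the best-ranked starts and
   keep the overall winner.

Per-curve fits use scipy's L-BFGS-B (least squares, with analytic
Jacobian) or Nelder-Mead (maximum likelihood).  Large homogeneous
batches are dispatched to a vectorised engine that performs the same
screen-then-polish scheme across all curves simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._batch import _screen_pairs, batch_fit
from .models import (
    PLATEAU_BOUNDS,
    SLOPE_BOUNDS,
    CurveData,
    LogisticParams,
    MeanFit,
    loglogistic_eval,
    loglogistic_gradient,
    mean_model_fit,
    pec50_bounds,
)

__all__ = [
    "FitBundle",
    "FitOptions",
    "build_start_grid",
    "fit_loglogistic",
    "fit_curves",
    "negative_log_likelihood",
    "InsufficientPointsError",
]

logger = logging.getLogger(__name__)

START_SLOPES = (0.5, 1.0, 2.0)
N_PEC50_STARTS = 7


class InsufficientPointsError(ValueError):
    """Curve has fewer usable points than the configured minimum."""


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the multi-start fit.

    ``min_points`` is the smallest usable n accepted for fitting
    (below it a curve is skipped); ``n_polish`` is how many top-ranked
    screen candidates receive a full local optimisation; ``tol`` is the
    objective convergence tolerance and ``maxiter`` the per-start
    iteration cap.
    """

    objective: str = "OLS"
    min_points: int = 5
    n_polish: int = 3
    tol: float = 1e-10
    maxiter: int = 500

    def __post_init__(self):
        if self.objective not in ("OLS", "MLE"):
            raise ValueError(f"objective must be OLS or MLE, got {self.objective!r}")


@dataclass
class FitBundle:
    """Everything downstream statistics need about one fitted curve."""

    curve_id: str
    params: LogisticParams
    sse_m1: float
    mean_fit: MeanFit
    sse_m0: float
    rmse_m0: float
    n: int
    converged: bool
    n_starts_used: int
    objective: str = "OLS"
    sigma2_mle: float | None = None
    x_min: float = float("nan")  # fitted log-dose range, for fold changes
    x_max: float = float("nan")


def build_start_grid(curve: CurveData, bounds=None) -> list[LogisticParams]:
    """Deterministic start candidates for the multi-start fit.

    pEC50 at 7 equally spaced positions across the experimental dose
    range, slope in {0.5, 1, 2}, plateaus from the 10th/90th
    percentiles of y in both orientations; duplicates removed.
    """
    x_min, x_max = curve.dose_range()
    pec_candidates = np.linspace(-x_max, -x_min, N_PEC50_STARTS)
    q10, q90 = np.percentile(curve.y, [10.0, 90.0])
    lo, hi = PLATEAU_BOUNDS
    q10, q90 = float(np.clip(q10, lo, hi)), float(np.clip(q90, lo, hi))
    seen = set()
    starts: list[LogisticParams] = []
    for pec in pec_candidates:
        for slope in START_SLOPES:
            for front, back in ((q90, q10), (q10, q90)):
                key = (round(float(pec), 12), slope, front, back)
                if key in seen:
                    continue
                seen.add(key)
                starts.append(LogisticParams(float(pec), slope, front, back))
    return starts


def negative_log_likelihood(params: LogisticParams, sigma2: float, curve: CurveData) -> float:
    """Gaussian negative log-likelihood of a curve under the model.

    negLL = n/2 * ln(2*pi*sigma2) + SSE / (2*sigma2); at fixed
    parameters the minimising sigma2 is SSE/n.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    resid = curve.y - loglogistic_eval(params, curve.x)
    sse = float((curve.w * resid * resid).sum())
    n = curve.n
    return 0.5 * n * np.log(2.0 * np.pi * sigma2) + sse / (2.0 * sigma2)


def _ols_objective(theta, x, y, w):
    p = LogisticParams.from_array(theta)
    r = loglogistic_eval(p, x) - y
    return float((w * r * r).sum())


def _ols_gradient(theta, x, y, w):
    p = LogisticParams.from_array(theta)
    r = loglogistic_eval(p, x) - y
    J = loglogistic_gradient(p, x)
    return 2.0 * (w * r) @ J


def _profiled_negll(theta, x, y, w, n):
    # sigma2 profiled out at SSE/n (closed-form stationary point)
    p = LogisticParams.from_array(theta)
    r = loglogistic_eval(p, x) - y
    sse = float((w * r * r).sum())
    sse = max(sse, 1e-300)
    return 0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)


def fit_loglogistic(
    curve: CurveData,
    bounds=None,
    objective: str | None = None,
    starts: list[LogisticParams] | None = None,
    options: FitOptions = FitOptions(),
) -> FitBundle:
    """Multi-start bounded fit of one curve; returns the best solution.

    Raises :class:`InsufficientPointsError` when the curve has fewer
    than ``options.min_points`` usable points.
    """
    objective = options.objective if objective is None else objective
    if curve.n < options.min_points:
        raise InsufficientPointsError(
            f"curve {curve.curve_id!r}: n={curve.n} < minimum {options.min_points}"
        )
    mean_fit, sse_m0 = mean_model_fit(curve)
    x_min, x_max = curve.dose_range()
    if bounds is None:
        pec_lb, pec_ub = pec50_bounds(x_min, x_max)
        bounds = [(pec_lb, pec_ub), SLOPE_BOUNDS, PLATEAU_BOUNDS, PLATEAU_BOUNDS]

    if starts is None:
        starts = build_start_grid(curve)
    # variable-projection screen ranks (pEC50, slope) candidates cheaply;
    # a denser slope set is added because step-like optima need slopes
    # well above the coarse start grid
    pairs = {(s.pec50, s.slope) for s in starts}
    pec_set = sorted({p for p, _ in pairs})
    for p in pec_set:
        for s in (4.0, 8.0, 16.0):
            pairs.add((p, s))
    pair_arr = np.array(sorted(pairs))
    Y = curve.y[None, :]
    W = curve.w[None, :]
    P, S, F, B, sse_scr = _screen_pairs(curve.x, Y, W, pair_arr)
    order = np.argsort(sse_scr[:, 0], kind="stable")

    best = None
    n_starts_used = 0
    converged = False
    scipy_bounds = [tuple(b) for b in bounds]
    for rank in range(min(options.n_polish, len(order))):
        i = int(order[rank])
        theta0 = np.clip(
            np.array([P[i], S[i], F[i, 0], B[i, 0]]),
            [b[0] for b in scipy_bounds],
            [b[1] for b in scipy_bounds],
        )
        res = minimize(
            _ols_objective,
            theta0,
            args=(curve.x, curve.y, curve.w),
            jac=_ols_gradient,
            method="L-BFGS-B",
            bounds=scipy_bounds,
            options={"ftol": options.tol, "gtol": 1e-12, "maxiter": options.maxiter},
        )
        n_starts_used += 1
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged

    # the flat curve (front = back = intercept) is inside the model
    # family, so the accepted fit can never be worse than the mean model
    flat = np.array(
        [0.5 * (scipy_bounds[0][0] + scipy_bounds[0][1]), 1.0,
         np.clip(mean_fit.intercept, *PLATEAU_BOUNDS),
         np.clip(mean_fit.intercept, *PLATEAU_BOUNDS)]
    )
    if best is None or best.fun > sse_m0:
        params = LogisticParams.from_array(flat)
        sse_m1 = sse_m0
        converged = best is not None
    else:
        params = LogisticParams.from_array(best.x)
        sse_m1 = float(best.fun)

    sigma2_mle = None
    if objective == "MLE":
        res = minimize(
            _profiled_negll,
            params.as_array(),
            args=(curve.x, curve.y, curve.w, curve.n),
            method="Nelder-Mead",
            bounds=scipy_bounds,
            options={"fatol": options.tol, "xatol": 1e-8, "maxiter": 4 * options.maxiter},
        )
        n_starts_used += 1
        cand = LogisticParams.from_array(res.x)
        r = curve.y - loglogistic_eval(cand, curve.x)
        sse_cand = float((curve.w * r * r).sum())
        if sse_cand <= sse_m1:
            params, sse_m1 = cand, sse_cand
        sigma2_mle = max(sse_m1, 1e-300) / curve.n

    rmse_m0 = float(np.sqrt(sse_m0 / curve.n))
    return FitBundle(
        curve_id=curve.curve_id,
        params=params,
        sse_m1=sse_m1,
        mean_fit=mean_fit,
        sse_m0=sse_m0,
        rmse_m0=rmse_m0,
        n=curve.n,
        converged=converged,
        n_starts_used=n_starts_used,
        objective=objective,
        sigma2_mle=sigma2_mle,
        x_min=x_min,
        x_max=x_max,
    )


def fit_curves(
    curves: list[CurveData],
    options: FitOptions = FitOptions(),
    use_batch: bool = True,
) -> tuple[list[FitBundle], list[tuple[str, str]]]:
    """Fit many curves; returns (bundles, skipped) with skip reasons.

    Curves sharing an identical dose grid and weights are fitted by the
    vectorised batch engine (same screen-then-polish scheme); the rest
    fall back to the per-curve scipy path.  Results are returned in the
    input order of the fittable curves.
    """
    bundles: dict[int, FitBundle] = {}
    skipped: list[tuple[str, str]] = []
    groups: dict[bytes, list[int]] = {}
    for i, c in enumerate(curves):
        if c.n < options.min_points:
            skipped.append((c.curve_id, f"n={c.n} below minimum {options.min_points}"))
            continue
        if use_batch and options.objective == "OLS":
            key = c.x.tobytes() + b"|" + c.w.tobytes()
            groups.setdefault(key, []).append(i)
        else:
            bundles[i] = fit_loglogistic(curves[i], options=options)

    for key, idxs in groups.items():
        if len(idxs) < 8:  # batching overhead not worth it
            for i in idxs:
                bundles[i] = fit_loglogistic(curves[i], options=options)
            continue
        x = curves[idxs[0]].x
        w = curves[idxs[0]].w
        Y = np.stack([curves[i].y for i in idxs])
        theta, sse1 = batch_fit(x, Y, W=w[None, :], n_polish=options.n_polish)
        for row, i in enumerate(idxs):
            c = curves[i]
            mean_fit, sse_m0 = mean_model_fit(c)
            bundles[i] = FitBundle(
                curve_id=c.curve_id,
                params=LogisticParams.from_array(theta[row]),
                sse_m1=float(min(sse1[row], sse_m0)),
                mean_fit=mean_fit,
                sse_m0=sse_m0,
                rmse_m0=float(np.sqrt(sse_m0 / c.n)),
                n=c.n,
                converged=True,
                n_starts_used=options.n_polish,
                objective="OLS",
                x_min=float(c.x[0]),
                x_max=float(c.x[-1]),
            )
    ordered = [bundles[i] for i in sorted(bundles)]
    for cid, reason in skipped:
        logger.info("skipped curve %s: %s", cid, reason)
    return ordered, skipped
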