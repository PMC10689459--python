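"""Vectorised fitting engine for large batches of curves sharing a dose grid.

Two stages, both fully vectorised across curves:

1.  Variable-projection screen.  For a fixed (pEC50, slope) the model is
    linear in (front, back): y = front*g + back*(1-g) with
    g = 1/(1+10**(slope*(x+pEC50))).  On a deterministic grid of
    (pEC50, slope) pairs the conditionally optimal plateaus solve a 2x2
    weighted least-squares system in closed form, so thousands of start
    candidates per curve cost a couple of matrix products.  Because the
    flat curve front = back = mean(y) is always feasible, the screened
    SSE never exceeds the mean-model SSE.

2.  Projected Levenberg-Marquardt polish.  The best few screened starts
    per curve are refined with a damped Gauss-Newton iteration whose
    steps are clipped to the box constraints; 4x4 normal systems are
    solved for all curves at once.

The engine is deterministic: no randomness, fixed iteration schedule.
"""

from __future__ import annotations

import numpy as np

from .models import LN10, PLATEAU_BOUNDS, SLOPE_BOUNDS, pec50_bounds

__all__ = ["batch_fit"]

# screening grid density: pEC50 positions across dose range +- 2 decades,
# slopes log-spaced through the allowed box to catch step-like optima
N_PEC_SCREEN = 25
SLOPES_SCREEN = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])


def _screen(x, Y, W, pec_grid, slope_grid):
    """Closed-form conditional plateau fit on a (pEC50, slope) grid.

    x: (n,), Y, W: (C, n).  Returns per-combo pec/slope vectors and the
    per (combo, curve) optimal front/back and weighted SSE.
    """
    P = np.repeat(pec_grid, len(slope_grid))
    S = np.tile(slope_grid, len(pec_grid))
    expo = np.clip(S[:, None] * (x[None, :] + P[:, None]), -300.0, 300.0)
    G = 1.0 / (1.0 + 10.0 ** expo)  # (M, n)
    H = 1.0 - G
    # weighted normal equations per (combo, curve)
    a = np.einsum("mn,cn->mc", G * G, W)
    b = np.einsum("mn,cn->mc", G * H, W)
    c = np.einsum("mn,cn->mc", H * H, W)
    WY = W * Y
    Gy = G @ WY.T  # (M, C)
    Hy = H @ WY.T
    det = a * c - b * b
    bad = np.abs(det) < 1e-300
    det = np.where(bad, 1.0, det)
    front = (c * Gy - b * Hy) / det
    back = (a * Hy - b * Gy) / det
    lo, hi = PLATEAU_BOUNDS
    front = np.clip(front, lo, hi)
    back = np.clip(back, lo, hi)
    # weighted SSE with the (possibly clipped) plateaus
    # sse = sum w*(f*g + b*h - y)^2 expanded with precomputed products
    yy = (W * Y * Y).sum(1)  # (C,)
    sse = (
        yy[None, :]
        + front * front * a
        + back * back * c
        + 2.0 * front * back * b
        - 2.0 * front * Gy
        - 2.0 * back * Hy
    )
    sse = np.where(bad, np.inf, np.maximum(sse, 0.0))
    return P, S, front, back, sse


def _residual_jac(theta, x, Y, W):
    """Weighted residuals and Jacobian for all curves. theta: (C, 4)."""
    p, s, f, b = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3], theta[:, 3:4]
    expo = np.clip(s * (x[None, :] + p), -300.0, 300.0)
    t = 10.0 ** expo
    g = 1.0 / (1.0 + t)
    yhat = b + (f - b) * g
    sw = np.sqrt(W)
    r = sw * (yhat - Y)
    dg = -t * g * g * LN10
    J = np.stack(
        [
            sw * (f - b) * dg * s,
            sw * (f - b) * dg * (x[None, :] + p),
            sw * g,
            sw * (1.0 - g),
        ],
        axis=2,
    )  # (C, n, 4)
    return r, J


def _sse(theta, x, Y, W):
    p, s, f, b = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3], theta[:, 3:4]
    expo = np.clip(s * (x[None, :] + p), -300.0, 300.0)
    g = 1.0 / (1.0 + 10.0 ** expo)
    r = b + (f - b) * g - Y
    return (W * r * r).sum(1)


def _lm_polish(x, Y, W, theta0, lb, ub, n_iter=60):
    """Projected Levenberg-Marquardt from one start per curve."""
    theta = np.clip(theta0, lb, ub)
    lam = np.full(len(theta), 1e-3)
    sse = _sse(theta, x, Y, W)
    idx4 = np.arange(4)
    for _ in range(n_iter):
        r, J = _residual_jac(theta, x, Y, W)
        JtJ = np.einsum("cni,cnj->cij", J, J)
        Jtr = np.einsum("cni,cn->ci", J, r)
        # Marquardt damping (lambda * diag) keeps the iteration exactly
        # equivariant under affine rescaling of the responses, so F-values
        # of rescaled noise draws agree to float precision
        diag = JtJ[:, idx4, idx4]
        floor = 1e-12 * diag.max(axis=1, keepdims=True) + 1e-300
        A = JtJ.copy()
        A[:, idx4, idx4] += lam[:, None] * np.maximum(diag, floor)
        try:
            delta = np.linalg.solve(A, -Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            diag = np.einsum("cii->ci", A)
            delta = -Jtr / np.where(np.abs(diag) < 1e-300, 1.0, diag)
        theta_new = np.clip(theta + delta, lb, ub)
        sse_new = _sse(theta_new, x, Y, W)
        improved = sse_new < sse
        theta = np.where(improved[:, None], theta_new, theta)
        sse = np.where(improved, sse_new, sse)
        lam = np.clip(np.where(improved, lam * 0.3, lam * 3.0), 1e-12, 1e9)
    return theta, sse


def batch_fit(
    x: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None = None,
    n_polish: int = 3,
    n_iter: int = 60,
    extra_starts: np.ndarray | None = None,
):
    """Fit the 4-parameter log-logistic model to every row of ``Y``.

    Parameters
    ----------
    x : (n,) shared log10 dose grid
    Y : (C, n) responses
    W : (C, n) weights, default all ones
    extra_starts : optional (K, 2) additional (pEC50, slope) screen pairs

    Returns
    -------
    theta : (C, 4) best-fit (pEC50, slope, front, back)
    sse : (C,) weighted SSE at the best fit
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    W = np.ones_like(Y) if W is None else np.broadcast_to(np.asarray(W, float), Y.shape)
    C = Y.shape[0]

    pec_lb, pec_ub = pec50_bounds(float(x.min()), float(x.max()))
    pec_grid = np.linspace(-float(x.max()) - 2.0, -float(x.min()) + 2.0, N_PEC_SCREEN)
    P, S, F, B, sse_grid = _screen(x, Y, W, pec_grid, SLOPES_SCREEN)
    if extra_starts is not None and len(extra_starts):
        P2, S2, F2, B2, sse2 = _screen_pairs(x, Y, W, np.asarray(extra_starts, float))
        P = np.concatenate([P, P2]); S = np.concatenate([S, S2])
        F = np.vstack([F, F2]); B = np.vstack([B, B2])
        sse_grid = np.vstack([sse_grid, sse2])

    lb = np.array([pec_lb, SLOPE_BOUNDS[0], PLATEAU_BOUNDS[0], PLATEAU_BOUNDS[0]])
    ub = np.array([pec_ub, SLOPE_BOUNDS[1], PLATEAU_BOUNDS[1], PLATEAU_BOUNDS[1]])

    order = np.argsort(sse_grid, axis=0, kind="stable")[:n_polish]  # (n_polish, C)
    cols = np.arange(C)
    best_theta = None
    best_sse = np.full(C, np.inf)
    for k in range(min(n_polish, order.shape[0])):
        idx = order[k]
        theta0 = np.stack([P[idx], S[idx], F[idx, cols], B[idx, cols]], axis=1)
        theta, sse = _lm_polish(x, Y, W, theta0, lb, ub, n_iter=n_iter)
        if best_theta is None:
            best_theta, best_sse = theta, sse
        else:
            better = sse < best_sse
            best_theta = np.where(better[:, None], theta, best_theta)
            best_sse = np.where(better, sse, best_sse)

    # safeguard: the flat curve is in the model family, so the fit must
    # never be worse than the mean model
    wsum = W.sum(1)
    ybar = (W * Y).sum(1) / wsum
    sse0 = (W * (Y - ybar[:, None]) ** 2).sum(1)
    worse = best_sse > sse0
    if np.any(worse):
        flat = np.stack(
            [
                np.full(C, 0.5 * (pec_lb + pec_ub)),
                np.ones(C),
                np.clip(ybar, *PLATEAU_BOUNDS),
                np.clip(ybar, *PLATEAU_BOUNDS),
            ],
            axis=1,
        )
        best_theta = np.where(worse[:, None], flat, best_theta)
        best_sse = np.where(worse, sse0, best_sse)
    return best_theta, best_sse


def _screen_pairs(x, Y, W, pairs):
    """Screen explicit (pEC50, slope) pairs instead of a product grid."""
    P = pairs[:, 0]
    S = pairs[:, 1]
    expo = np.clip(S[:, None] * (x[None, :] + P[:, None]), -300.0, 300.0)
    G = 1.0 / (1.0 + 10.0 ** expo)
    H = 1.0 - G
    a = np.einsum("mn,cn->mc", G * G, W)
    b = np.einsum("mn,cn->mc", G * H, W)
    c = np.einsum("mn,cn->mc", H * H, W)
    WY = W * Y
    Gy = G @ WY.T
    Hy = H @ WY.T
    det = a * c - b * b
    bad = np.abs(det) < 1e-300
    det = np.where(bad, 1.0, det)
    lo, hi = PLATEAU_BOUNDS
    front = np.clip((c * Gy - b * Hy) / det, lo, hi)
    back = np.clip((a * Hy - b * Gy) / det, lo, hi)
    yy = (W * Y * Y).sum(1)
    sse = (
        yy[None, :]
        + front * front * a
        + back * back * c
        + 2.0 * front * back * b
        - 2.0 * front * Gy
        - 2.0 * back * Hy
    )
    sse = np.where(bad, np.inf, np.maximum(sse, 0.0))
    return P, S, front, back, sse
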