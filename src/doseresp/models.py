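"""Competing response models for dose-response curves.

Two models are compared for every curve: a constant "mean" model (the
null model: response is independent of dose) and a four-parameter
log-logistic model

    y(x) = back + (front - back) / (1 + 10**(slope * (x + pEC50)))

where ``x`` is the log10 of the molar concentration, ``pEC50`` is the
negative log10 of the half-maximal effective concentration, ``slope`` is
a positive Hill-type steepness, and ``front``/``back`` are the low-dose
and high-dose plateau responses (ratio-to-control units).  With this
parameterisation the inflection point sits at ``x = -pEC50``,
``y -> front`` as ``x -> -inf`` and ``y -> back`` as ``x -> +inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurveData",
    "LogisticParams",
    "MeanFit",
    "SLOPE_BOUNDS",
    "PLATEAU_BOUNDS",
    "loglogistic_eval",
    "loglogistic_gradient",
    "mean_model_fit",
    "fold_change",
    "pec50_bounds",
    "InvalidParameterError",
    "EmptyCurveError",
]

LN10 = float(np.log(10.0))

#: hard box constraints used by the fitting routines
SLOPE_BOUNDS = (0.01, 20.0)
PLATEAU_BOUNDS = (1e-3, 1e6)

#: pEC50 is allowed this many decades beyond the experimental dose range
PEC50_MARGIN = 4.0


class InvalidParameterError(ValueError):
    """Model parameters are non-finite or outside their domain."""


class EmptyCurveError(ValueError):
    """A curve with zero usable data points was passed to a fit."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameter vector Theta of the log-logistic model."""

    pec50: float
    slope: float
    front: float
    back: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pec50, self.slope, self.front, self.back], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "LogisticParams":
        p, s, f, b = (float(v) for v in theta)
        return cls(p, s, f, b)

    def validate(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError(f"non-finite parameters: {self}")
        if self.slope <= 0:
            raise InvalidParameterError(f"slope must be positive, got {self.slope}")


@dataclass
class CurveData:
    """One dose-response curve: log10 doses, responses and weights.

    ``x`` holds log10 molar concentrations (including the control's
    pseudo log-dose when a control point is used), ``y`` the responses
    as ratios to control, ``w`` non-negative weights.  Arrays are kept
    sorted by ``x``; non-finite pairs are dropped on construction and
    ``n`` counts the retained points.
    """

    curve_id: str
    x: np.ndarray
    y: np.ndarray
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        w = np.ones_like(x) if self.w is None else np.asarray(self.w, dtype=float)
        if not (len(x) == len(y) == len(w)):
            raise ValueError(
                f"curve {self.curve_id!r}: x, y, w lengths differ "
                f"({len(x)}, {len(y)}, {len(w)})"
            )
        keep = np.isfinite(x) & np.isfinite(y) & (y > 0)
        x, y, w = x[keep], y[keep], w[keep]
        order = np.argsort(x, kind="stable")
        self.x, self.y, self.w = x[order], y[order], w[order]
        self.n = int(len(self.x))

    def dose_range(self) -> tuple[float, float]:
        if self.n == 0:
            raise EmptyCurveError(f"curve {self.curve_id!r} has no usable points")
        return float(self.x[0]), float(self.x[-1])


@dataclass(frozen=True)
class MeanFit:
    """Analytical fit of the constant (mean) model."""

    intercept: float


def pec50_bounds(x_min: float, x_max: float, margin: float = PEC50_MARGIN) -> tuple[float, float]:
    """Allowed pEC50 interval: experimental dose range +- ``margin`` decades.

    The inflection sits at x = -pEC50, so pEC50 candidates span
    [-x_max - margin, -x_min + margin].
    """
    return (-x_max - margin, -x_min + margin)


def loglogistic_eval(params: LogisticParams, x) -> np.ndarray:
    """Evaluate the four-parameter log-logistic model at log-dose ``x``."""
    params.validate()
    x = np.asarray(x, dtype=float)
    expo = np.clip(params.slope * (x + params.pec50), -300.0, 300.0)
    g = 1.0 / (1.0 + 10.0 ** expo)
    return params.back + (params.front - params.back) * g


def loglogistic_gradient(params: LogisticParams, x) -> np.ndarray:
    """Partial derivatives of the model w.r.t. (pEC50, slope, front, back).

    Returns an array of shape (len(x), 4) matching the parameter order of
    :class:`LogisticParams`.  Used as the Jacobian in gradient-based fits.
    """
    params.validate()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    expo = np.clip(params.slope * (x + params.pec50), -300.0, 300.0)
    t = 10.0 ** expo
    g = 1.0 / (1.0 + t)
    dg_dexpo = -t * g * g * LN10  # d g / d expo
    amp = params.front - params.back
    d_pec50 = amp * dg_dexpo * params.slope
    d_slope = amp * dg_dexpo * (x + params.pec50)
    d_front = g
    d_back = 1.0 - g
    return np.stack([d_pec50, d_slope, d_front, d_back], axis=1)


def mean_model_fit(curve: CurveData) -> tuple[MeanFit, float]:
    """Weighted analytical fit of the mean model; returns (fit, SSE).

    intercept = sum(w*y)/sum(w), SSE = sum(w*(y - intercept)^2).
    """
    if curve.n == 0:
        raise EmptyCurveError(f"curve {curve.curve_id!r} is empty")
    wsum = float(curve.w.sum())
    if wsum <= 0:
        raise ValueError(f"curve {curve.curve_id!r}: total weight is zero")
    intercept = float((curve.w * curve.y).sum() / wsum)
    sse = float((curve.w * (curve.y - intercept) ** 2).sum())
    return MeanFit(intercept), sse


def fold_change(
    params: LogisticParams,
    x_min: float,
    x_max: float,
    mode: str = "range",
    y_control: float = 1.0,
) -> float:
    """Curve fold change: log2 effect size of the fitted curve.

    mode="range" compares the model prediction at the highest vs the
    lowest dose of the fitted x-range; mode="control" compares the
    prediction at the highest dose to the control response (1.0 under
    ratio normalisation).  Positive values mean up-regulation.
    """
    y_hi = float(loglogistic_eval(params, x_max))
    if mode == "range":
        y_lo = float(loglogistic_eval(params, x_min))
    elif mode == "control":
        y_lo = float(y_control)
    else:
        raise ValueError(f"unknown fold-change mode {mode!r}")
    if params.front == params.back:
        return 0.0
    if y_hi <= 0 or y_lo <= 0:
        raise ValueError("fold change undefined for non-positive model values")
    return float(np.log2(y_hi) - np.log2(y_lo))
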