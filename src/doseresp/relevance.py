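"""Relevance scores and hyperbolic decision boundaries.

Significance alone over-rewards curves with tiny effect sizes.  In the
SAM tradition a fudge factor s0 is added so that the decision boundary
in the volcano plot becomes a hyperbola with a significance asymptote
(alpha) and a fold-change asymptote (fc_lim): no curve with
|cfc| < fc_lim can ever be called regulated, however significant.

s0 is derived from the two asymptotes and the curve's effective df:

    s0 = fc_lim / sqrt(Q),  Q = central F quantile at 1 - alpha

Each curve's F is shrunk toward zero according to its fold change,

    F_adj = 1 / (1/sqrt(F) + s0/|cfc|)**2

and F_adj is converted into a relevance score, the -log10 upper-tail
probability under the same shifted null used for p-values.  With
s0 = 0 the relevance score is exactly -log10(p).  A curve is called
regulated when its relevance score reaches -log10(alpha).

Note on conventions: the s0 quantile uses the central (unshifted) F
distribution while the relevance tail uses the shifted null
(loc = 0.12).  This mixed convention reproduces the published worked
s0 values and keeps the s0 = 0 reduction to the p-value exact; both
pieces are overridable via :class:`FCalibration` / ``use_shifted_tail``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import FitBundle
from .significance import DEFAULT_CALIBRATION, FCalibration, effective_dfd

__all__ = [
    "Boundary",
    "CurveStatistics",
    "NotRegulatedRule",
    "compute_s0",
    "adjusted_f",
    "relevance_score",
    "classify_curve",
    "hyperbolic_boundary_test",
]


def compute_s0(
    alpha_asymptote: float,
    fc_asymptote: float,
    n: int,
    calib: FCalibration = DEFAULT_CALIBRATION,
    use_shifted_quantile: bool = False,
) -> float:
    """Tuning parameter s0 from the two user-specified asymptotes.

    Uses the central F quantile by default (see module note); s0 = 0
    when the fold-change asymptote is zero.
    """
    if not 0.0 < alpha_asymptote < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha_asymptote}")
    if fc_asymptote < 0:
        raise ValueError(f"fc_asymptote must be >= 0, got {fc_asymptote}")
    if fc_asymptote == 0.0:
        return 0.0
    dfd = effective_dfd(n, calib.k)
    loc = calib.loc if use_shifted_quantile else 0.0
    q = stats.f.ppf(1.0 - alpha_asymptote, calib.dfn, dfd, loc=loc, scale=calib.scale)
    return float(fc_asymptote / np.sqrt(q))


@dataclass
class Boundary:
    """A hyperbolic decision boundary defined by its two asymptotes."""

    alpha_asymptote: float
    fc_asymptote: float
    calib: FCalibration = DEFAULT_CALIBRATION
    _s0_cache: dict = field(default_factory=dict, repr=False)

    def s0_for_n(self, n: int) -> float:
        """s0 for a curve with n points (cached; depends on n via dfd)."""
        if n not in self._s0_cache:
            self._s0_cache[n] = compute_s0(
                self.alpha_asymptote, self.fc_asymptote, n, self.calib
            )
        return self._s0_cache[n]

    @property
    def relevance_threshold(self) -> float:
        return float(-np.log10(self.alpha_asymptote))


@dataclass
class CurveStatistics:
    """Per-curve significance and relevance summary."""

    curve_id: str
    f: float
    dfd: float
    p: float
    cfc: float
    f_adj: float
    relevance: float
    n: int
    q: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class NotRegulatedRule:
    """Heuristic for confidently flat ("not regulated") curves.

    A clear non-responder has a mean-model intercept close to 1
    (|log2 intercept| <= fc_lim/2 by default; linear space optional)
    and low variance around the flat model (RMSE <= rmse_limit).
    ``not_p_min`` optionally also requires the curve to be clearly
    non-significant (p >= not_p_min).
    """

    rmse_limit: float = 0.1
    intercept_log2: bool = True
    not_p_min: float | None = None


def adjusted_f(f: float, cfc: float, s0: float) -> float:
    """s0-adjusted F-value; shrinks F toward 0 for small effect sizes.

    Uses |cfc| so down-regulations are penalised symmetrically.  By
    the continuity convention F_adj = 0 when F = 0 or when cfc = 0
    with s0 > 0.
    """
    if f < 0 or s0 < 0:
        raise ValueError("f and s0 must be non-negative")
    if s0 == 0.0:
        return float(f)
    if f == 0.0 or cfc == 0.0:
        return 0.0
    if np.isinf(f):
        return float((abs(cfc) / s0) ** 2)
    with np.errstate(over="ignore"):  # extreme s0/|cfc| squares to inf -> 0
        return float(1.0 / (1.0 / np.sqrt(f) + s0 / abs(cfc)) ** 2)


def relevance_score(
    f_adj: float,
    n: int,
    calib: FCalibration = DEFAULT_CALIBRATION,
    use_shifted_tail: bool = True,
) -> float:
    """-log10 upper-tail probability of the adjusted F under the null.

    Monotone increasing in f_adj; 0 means no relevance.  With s0 = 0
    (f_adj = f) this equals -log10 of the curve's p-value.
    """
    if f_adj < 0:
        raise ValueError(f"f_adj must be >= 0, got {f_adj}")
    dfd = effective_dfd(n, calib.k)
    loc = calib.loc if use_shifted_tail else 0.0
    tail = stats.f.sf(f_adj, calib.dfn, dfd, loc=loc, scale=calib.scale)
    if tail <= 0.0:
        return float("inf")
    return float(-np.log10(tail))


def hyperbolic_boundary_test(
    f: float, cfc: float, boundary: Boundary, n: int
) -> bool:
    """True iff the (F, cfc) point lies on the regulated side.

    Exactly equivalent to thresholding the relevance score at
    -log10(alpha); exposed separately as the explicit volcano-plot
    boundary form.
    """
    s0 = boundary.s0_for_n(n)
    score = relevance_score(adjusted_f(f, cfc, s0), n, boundary.calib)
    return bool(score >= boundary.relevance_threshold)


def classify_curve(
    stats_: CurveStatistics,
    fit: FitBundle,
    boundary: Boundary,
    not_rule: NotRegulatedRule = NotRegulatedRule(),
) -> str:
    """Assign one of {up, down, not, unclear} to a curve.

    Regulated (up/down by the sign of the fold change) when the
    relevance score reaches the boundary threshold; otherwise "not"
    only if the curve is confidently flat; everything else "unclear".
    """
    if stats_.relevance >= boundary.relevance_threshold and stats_.cfc != 0.0:
        return "up" if stats_.cfc > 0 else "down"
    intercept = fit.mean_fit.intercept
    if not_rule.intercept_log2:
        flat_enough = (
            intercept > 0
            and abs(np.log2(intercept)) <= boundary.fc_asymptote / 2.0
        )
    else:
        flat_enough = abs(intercept - 1.0) <= boundary.fc_asymptote / 2.0
    quiet_enough = fit.rmse_m0 <= not_rule.rmse_limit
    p_ok = not_rule.not_p_min is None or stats_.p >= not_rule.not_p_min
    if flat_enough and quiet_enough and p_ok:
        return "not"
    return "unclear"
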