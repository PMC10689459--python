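"""Target-decoy false discovery rate estimation for curve calling.

Decoy curves are flat-truth curves whose noise is drawn from the
dataset's own per-curve sample variances (SSE of the fitted model
divided by the effective df), pushed through the identical fitting and
scoring pipeline.  Comparing how many decoys versus targets exceed a
relevance-score threshold yields an FDR estimate for that threshold
and a q-value per curve.

Counting uses ">= with self-inclusion" plus a decoy-to-target
rescaling factor, and q-values are monotonised (each curve's q is the
minimum raw FDR over all thresholds at or below its own score), the
standard target-decoy conventions that avoid 0/0 and q > 1 artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .fitting import FitBundle
from .models import CurveData
from .significance import effective_dfd

__all__ = [
    "DecoyModel",
    "QValueTable",
    "estimate_variances",
    "generate_decoys",
    "compute_qvalues",
    "fdr_at_boundary",
    "bh_qvalues",
]

logger = logging.getLogger(__name__)


@dataclass
class DecoyModel:
    """Empirical variance sample of the dataset plus decoy settings."""

    variance_sample: np.ndarray
    n_decoys: int
    seed: int = 0

    def __post_init__(self):
        self.variance_sample = np.asarray(self.variance_sample, dtype=float)
        self.variance_sample = self.variance_sample[self.variance_sample > 0]
        if len(self.variance_sample) == 0:
            raise ValueError("variance sample is empty after filtering")
        if self.n_decoys < 100:
            logger.warning(
                "n_decoys=%d is small; q-values will be unstable below ~100 decoys",
                self.n_decoys,
            )


@dataclass
class QValueTable:
    """Per-target q-values (input order) and the FDR at the boundary."""

    q: np.ndarray
    global_fdr_at_boundary: float | None = None


def estimate_variances(fits: list[FitBundle]) -> np.ndarray:
    """Per-curve sample variances s_i^2 = SSE_M1 / dfd(n_i).

    Curves with zero residual SSE are excluded (logged) since they
    carry no noise information.
    """
    out = []
    n_excluded = 0
    for fb in fits:
        if fb.sse_m1 <= 0.0:
            n_excluded += 1
            continue
        out.append(fb.sse_m1 / effective_dfd(fb.n))
    if n_excluded:
        logger.info("excluded %d zero-residual curves from variance estimation", n_excluded)
    return np.asarray(out, dtype=float)


def generate_decoys(model: DecoyModel, x: np.ndarray) -> list[CurveData]:
    """Flat-truth decoy curves with variances resampled from the data."""
    rng = np.random.default_rng(model.seed)
    x = np.asarray(x, dtype=float)
    var = rng.choice(model.variance_sample, size=model.n_decoys, replace=True)
    Y = 1.0 + rng.standard_normal((model.n_decoys, len(x))) * np.sqrt(var)[:, None]
    return [
        CurveData(curve_id=f"decoy_{i}", x=x.copy(), y=Y[i])
        for i in range(model.n_decoys)
    ]


def _raw_fdrs(target_scores: np.ndarray, decoy_scores: np.ndarray) -> np.ndarray:
    """Raw FDR at each target's own score threshold (>= counting)."""
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError("target and decoy score lists must be non-empty")
    scale = len(t) / len(d)
    d_sorted = np.sort(d)
    t_sorted = np.sort(t)
    # counts of decoys / targets with score >= each target score
    n_d = len(d) - np.searchsorted(d_sorted, t, side="left")
    n_t = len(t) - np.searchsorted(t_sorted, t, side="left")  # includes self
    return np.clip(n_d * scale / n_t, 0.0, 1.0)


def compute_qvalues(target_scores, decoy_scores) -> QValueTable:
    """q-value per target: minimal estimated FDR at which it is called.

    q_i = min over thresholds at or below score_i of the raw FDR,
    i.e. a suffix-minimum over targets ordered by decreasing score.
    """
    t = np.asarray(target_scores, dtype=float)
    raw = _raw_fdrs(t, decoy_scores)
    order = np.argsort(-t, kind="stable")  # decreasing score
    q_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return QValueTable(q=q)


def fdr_at_boundary(target_scores, decoy_scores, boundary_threshold: float) -> float:
    """Estimated FDR among curves at or above a score threshold.

    Returns NaN when no target reaches the threshold.
    """
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError("target and decoy score lists must be non-empty")
    n_t = int((t >= boundary_threshold).sum())
    if n_t == 0:
        return float("nan")
    n_d = int((d >= boundary_threshold).sum())
    return float(min(n_d * (len(t) / len(d)) / n_t, 1.0))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (comparison utility)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
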