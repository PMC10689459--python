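"""Synthetic dose-response datasets with known ground truth.

Generates flat-truth (null) curves, regulated log-logistic curves, and
shuffled mixtures of both, together with truth tables, so that every
pipeline stage can be exercised and benchmarked without external data.

The per-curve noise level is drawn from a truncated log-normal
stand-in for the spread of variances seen in deep proteomics
dose-response experiments (log10 sigma ~ Normal(-1.3, 0.35), truncated
to sigma in [0.005, 0.5]).  The stand-in's parameters are synthetic
choices of this package, kept in one place below; they are not
measured values from any particular experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import CurveData, LogisticParams, loglogistic_eval

__all__ = [
    "MixtureSpec",
    "VARIANCE_STANDIN",
    "draw_sigma",
    "make_null_dataset",
    "make_regulated_dataset",
    "make_mixture_dataset",
    "dataset_to_frame",
    "write_dataset",
]

#: synthetic stand-in for an empirical variance distribution:
#: log10(sigma) ~ Normal(mu, sd), truncated to [lo, hi] on sigma
VARIANCE_STANDIN = {"mu": -1.3, "sd": 0.35, "lo": 0.005, "hi": 0.5}


def draw_sigma(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-curve noise SDs from the truncated log-normal stand-in."""
    sigma = 10.0 ** rng.normal(VARIANCE_STANDIN["mu"], VARIANCE_STANDIN["sd"], n)
    return np.clip(sigma, VARIANCE_STANDIN["lo"], VARIANCE_STANDIN["hi"])


@dataclass
class MixtureSpec:
    """Study design of a synthetic dataset.

    The dose grid has ``n_doses`` log-equispaced points spanning
    ``decades`` decades ending at ``log_dose_max`` (log10 molar).
    Regulated curves draw truth pEC50 uniformly at least
    ``pec50_margin`` decades inside the dose range, slope from
    ``slope_range`` (or fixed when both ends equal), and a signed log2
    fold change whose magnitude is uniform in ``cfc_range`` with the
    direction chosen up/down with equal probability.  ``sigma`` fixes
    the noise SD for every curve when given; otherwise per-curve SDs
    come from the variance stand-in.
    """

    n_curves: int = 1000
    fraction_regulated: float = 0.1
    n_doses: int = 10
    decades: float = 5.0
    log_dose_max: float = -4.0
    pec50_margin: float = 1.0
    slope_range: tuple[float, float] = (1.0, 1.0)
    cfc_range: tuple[float, float] = (0.5, 2.0)
    sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ValueError("fraction_regulated must be in [0, 1]")
        if self.n_doses < 5:
            raise ValueError("dose grid needs >= 5 points")

    @property
    def doses_log10(self) -> np.ndarray:
        return np.linspace(
            self.log_dose_max - self.decades, self.log_dose_max, self.n_doses
        )


def _sigmas(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.sigma is not None:
        return np.full(n, float(spec.sigma))
    return draw_sigma(n, rng)


def make_null_dataset(
    spec: MixtureSpec, seed: int | None = None, id_prefix: str = "curve"
) -> tuple[list[CurveData], pd.DataFrame]:
    """Flat-truth curves y = 1 + noise; truth table labels all 'null'."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = spec.doses_log10
    sigma = _sigmas(spec, spec.n_curves, rng)
    Y = 1.0 + rng.standard_normal((spec.n_curves, spec.n_doses)) * sigma[:, None]
    curves = [
        CurveData(curve_id=f"{id_prefix}_{i}", x=x.copy(), y=Y[i])
        for i in range(spec.n_curves)
    ]
    truth = pd.DataFrame(
        {
            "curve_id": [c.curve_id for c in curves],
            "label": "null",
            "pec50": np.nan,
            "slope": np.nan,
            "cfc": 0.0,
            "sigma": sigma,
        }
    )
    return curves, truth


def make_regulated_dataset(
    spec: MixtureSpec, seed: int | None = None, id_prefix: str = "curve"
) -> tuple[list[CurveData], pd.DataFrame]:
    """Log-logistic truth curves plus Gaussian noise, with a truth table.

    The front plateau is 1 (ratio units); the back plateau is
    2**cfc_truth so the saturated curve fold change equals the drawn
    signed magnitude.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = spec.doses_log10
    n = spec.n_curves
    lo = -float(x.max()) + spec.pec50_margin
    hi = -float(x.min()) - spec.pec50_margin
    pec50 = rng.uniform(lo, hi, n)
    slope = (
        np.full(n, spec.slope_range[0])
        if spec.slope_range[0] == spec.slope_range[1]
        else rng.uniform(*spec.slope_range, n)
    )
    mag = rng.uniform(*spec.cfc_range, n)
    sign = rng.choice([-1.0, 1.0], n)
    cfc = sign * mag
    sigma = _sigmas(spec, n, rng)
    curves = []
    for i in range(n):
        params = LogisticParams(pec50[i], slope[i], 1.0, float(2.0 ** cfc[i]))
        y = loglogistic_eval(params, x) + rng.standard_normal(spec.n_doses) * sigma[i]
        curves.append(CurveData(curve_id=f"{id_prefix}_{i}", x=x.copy(), y=y))
    truth = pd.DataFrame(
        {
            "curve_id": [c.curve_id for c in curves],
            "label": np.where(cfc > 0, "up", "down"),
            "pec50": pec50,
            "slope": slope,
            "cfc": cfc,
            "sigma": sigma,
        }
    )
    return curves, truth


def make_mixture_dataset(
    spec: MixtureSpec, seed: int | None = None
) -> tuple[list[CurveData], pd.DataFrame]:
    """Shuffled mixture of null and regulated curves with truth labels."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_reg = int(round(spec.n_curves * spec.fraction_regulated))
    n_null = spec.n_curves - n_reg
    parts_c: list[CurveData] = []
    parts_t = []
    if n_null:
        null_spec = _with(spec, n_curves=n_null)
        c, t = make_null_dataset(null_spec, seed=_child_seed(seed, 1), id_prefix="tmpn")
        parts_c += c
        parts_t.append(t)
    if n_reg:
        reg_spec = _with(spec, n_curves=n_reg)
        c, t = make_regulated_dataset(reg_spec, seed=_child_seed(seed, 2), id_prefix="tmpr")
        parts_c += c
        parts_t.append(t)
    truth = pd.concat(parts_t, ignore_index=True)
    order = rng.permutation(len(parts_c))
    curves = [parts_c[i] for i in order]
    truth = truth.iloc[order].reset_index(drop=True)
    for i, c in enumerate(curves):
        c.curve_id = f"curve_{i}"
    truth["curve_id"] = [c.curve_id for c in curves]
    return curves, truth


def _with(spec: MixtureSpec, **kw) -> MixtureSpec:
    d = {f: getattr(spec, f) for f in spec.__dataclass_fields__}
    d.update(kw)
    return MixtureSpec(**d)


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def dataset_to_frame(curves: list[CurveData], doses_log10: np.ndarray) -> pd.DataFrame:
    """Wide table (one row per curve, one response column per dose)."""
    cols = [f"dose_{i+1}" for i in range(len(doses_log10))]
    grid = np.asarray(doses_log10, dtype=float)
    rows = {}
    for c in curves:
        pos = np.searchsorted(grid, c.x)
        if np.any(pos >= len(grid)) or not np.allclose(grid[pos], c.x):
            raise ValueError(f"curve {c.curve_id} is not on the shared dose grid")
        row = np.full(len(grid), np.nan)
        row[pos] = c.y  # points dropped as unusable become missing cells
        rows[c.curve_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "curve_id"
    return df.reset_index()


def write_dataset(
    curves: list[CurveData],
    truth: pd.DataFrame,
    doses_log10: np.ndarray,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the canonical TSV dialect plus a truth TSV; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / "curves.tsv"
    truth_path = out_dir / "truth.tsv"
    dataset_to_frame(curves, doses_log10).to_csv(data_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    return data_path, truth_path
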