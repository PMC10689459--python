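"""Input tables, TOML configuration, preprocessing, and result output.

The canonical input dialect is a wide TSV/CSV: one row per curve, an id
column, one response column per dose plus optional control columns.
The TOML parameter file names those columns and gives the molar doses
in matching order, alongside fitting, statistic, classification and
FDR options.

Preprocessing follows the order median-centering -> imputation ->
ratio normalisation to the control mean, each stage opt-in.  A control
measurement has no position on a log-dose axis, so control points are
anchored at a pseudo log-dose ``min(log10 dose) - control_offset``
(default two decades below the lowest real dose) where they pin the
front plateau.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
import tomllib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .models import CurveData

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "read_table",
    "normalize_to_control",
    "median_center",
    "impute_missing",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The TOML parameter file is inconsistent or incomplete."""


@dataclass
class PipelineConfig:
    """All pipeline settings, flat; (de)serialised to sectioned TOML."""

    # [experiment]
    doses: list[float] = field(default_factory=list)  # molar, per response column
    response_columns: list[str] = field(default_factory=list)
    control_columns: list[str] = field(default_factory=list)
    dose_scale: float = 1.0  # multiply doses by this to get molar
    control_offset: float = 2.0  # decades below min dose for the control point
    median_center: bool = False
    impute_enabled: bool = False
    impute_quantile: float = 0.005
    max_missing: int = 4
    seed: int = 0
    # [io]
    input_path: str = ""
    output_path: str = "results.tsv"
    id_column: str = "curve_id"
    delimiter: str = "\t"
    plot_dir: str = ""
    # [fit]
    objective: str = "OLS"
    min_points: int = 5
    n_polish: int = 3
    # [statistic]
    dfn: float = 5.0
    loc: float = 0.12
    scale: float = 1.0
    fc_mode: str = "range"
    # [classification]
    alpha: float = 0.05
    fc_lim: float = 0.45
    rmse_limit: float = 0.1
    not_p_min: float = -1.0  # <= 0 disables the extra p criterion
    intercept_log2: bool = True
    # [fdr]
    fdr_enabled: bool = False
    n_decoys: int = 0  # 0 -> same as number of targets

    _SECTIONS = {
        "experiment": [
            "doses", "response_columns", "control_columns", "dose_scale",
            "control_offset", "median_center", "impute_enabled",
            "impute_quantile", "max_missing", "seed",
        ],
        "io": ["input_path", "output_path", "id_column", "delimiter", "plot_dir"],
        "fit": ["objective", "min_points", "n_polish"],
        "statistic": ["dfn", "loc", "scale", "fc_mode"],
        "classification": ["alpha", "fc_lim", "rmse_limit", "not_p_min", "intercept_log2"],
        "fdr": ["fdr_enabled", "n_decoys"],
    }

    def __post_init__(self):
        if self.doses and self.response_columns and len(self.doses) != len(self.response_columns):
            raise ConfigError(
                f"{len(self.doses)} doses but {len(self.response_columns)} response columns"
            )
        if any(d <= 0 for d in self.doses):
            raise ConfigError("doses must be positive molar concentrations")
        if not 0.0 < self.impute_quantile < 0.5:
            raise ConfigError("imputation quantile must be in (0, 0.5)")

    @property
    def doses_log10(self) -> np.ndarray:
        return np.log10(np.asarray(self.doses, dtype=float) * self.dose_scale)

    @property
    def control_log_dose(self) -> float:
        return float(self.doses_log10.min() - self.control_offset)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        known = {f.name for f in dc_fields(cls) if not f.name.startswith("_")}
        for section, keys in cls._SECTIONS.items():
            for key, val in raw.get(section, {}).items():
                if key not in known:
                    raise ConfigError(f"unknown key {key!r} in section [{section}]")
                kwargs[key] = val
        return cls(**kwargs)

    def to_toml(self, path: str | Path | None = None) -> str:
        lines = []
        for section, keys in self._SECTIONS.items():
            lines.append(f"[{section}]")
            for key in keys:
                lines.append(f"{key} = {_toml_value(getattr(self, key))}")
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"').replace("\t", "\\t") + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def median_center(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Multiplicative per-column median centering in intensity space.

    Each column is divided by its own median (missing cells ignored)
    and rescaled to the grand median of the selected columns.
    """
    out = frame.copy()
    medians = out[columns].median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"columns with no finite values: {bad}")
    grand = float(np.nanmedian(out[columns].to_numpy(dtype=float)))
    for col in columns:
        out[col] = out[col] / medians[col] * grand
    return out


def impute_missing(frame: pd.DataFrame, columns: list[str], quantile: float = 0.005):
    """Replace missing cells by the per-table low-intensity quantile.

    Returns (frame, n_imputed).
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError(f"imputation quantile must be in (0, 0.5), got {quantile}")
    out = frame.copy()
    values = out[columns].to_numpy(dtype=float)
    observed = values[np.isfinite(values)]
    fill = float(np.quantile(observed, quantile))
    mask = ~np.isfinite(values)
    n_imputed = int(mask.sum())
    values[mask] = fill
    out[columns] = values
    if n_imputed:
        logger.info("imputed %d missing cells with the %.3g quantile (%.4g)",
                    n_imputed, quantile, fill)
    return out, n_imputed


def normalize_to_control(frame: pd.DataFrame, response_columns: list[str],
                         control_columns: list[str]):
    """Divide each row by the mean of its control columns.

    Rows whose control mean is not positive are dropped (returned in
    the exclusion list).  Returns (frame, excluded_row_indices).
    """
    out = frame.copy()
    ctrl = out[control_columns].mean(axis=1, skipna=True)
    bad = ~(ctrl > 0) | ~np.isfinite(ctrl)
    excluded = list(out.index[bad])
    out = out.loc[~bad].copy()
    all_cols = list(response_columns) + list(control_columns)
    out[all_cols] = out[all_cols].div(ctrl.loc[~bad], axis=0)
    if excluded:
        logger.warning("excluded %d rows with non-positive control mean", len(excluded))
    return out, excluded


def read_table(path: str | Path, config: PipelineConfig):
    """Read, preprocess and convert a wide table into curves.

    Applies (in order, each opt-in): median centering, low-quantile
    imputation, ratio normalisation to the control mean.  Rows with
    more than ``max_missing`` missing response cells are excluded.
    Returns (curves, ledger) where the ledger maps curve ids to
    exclusion reasons for every dropped row.
    """
    frame = pd.read_csv(path, sep=config.delimiter, dtype={config.id_column: str})
    if len(frame) == 0:
        raise ValueError(f"input table {path} is empty")
    missing_cols = [
        c for c in [config.id_column, *config.response_columns, *config.control_columns]
        if c not in frame.columns
    ]
    if missing_cols:
        raise ValueError(f"input table lacks columns: {missing_cols}")
    dup = frame[config.id_column].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate curve ids at rows {list(frame.index[dup])}: "
            f"{frame.loc[dup, config.id_column].tolist()[:5]}"
        )
    frame = frame.set_index(config.id_column)

    data_cols = list(config.response_columns) + list(config.control_columns)
    ledger: dict[str, str] = {}

    n_missing = frame[config.response_columns].isna().sum(axis=1)
    too_sparse = n_missing > config.max_missing
    for cid in frame.index[too_sparse]:
        ledger[str(cid)] = (
            f"{int(n_missing[cid])} missing values exceed max_missing={config.max_missing}"
        )
    frame = frame.loc[~too_sparse]

    if config.median_center:
        frame = median_center(frame, data_cols)
    if config.impute_enabled:
        frame, _ = impute_missing(frame, data_cols, config.impute_quantile)
    if config.control_columns:
        frame, excluded = normalize_to_control(
            frame, config.response_columns, config.control_columns
        )
        for cid in excluded:
            ledger[str(cid)] = "non-positive control mean"

    x_doses = config.doses_log10
    curves = []
    for cid, row in frame.iterrows():
        y = row[config.response_columns].to_numpy(dtype=float)
        x = x_doses.copy()
        if config.control_columns:
            ctrl_y = row[config.control_columns].to_numpy(dtype=float)
            keep = np.isfinite(ctrl_y)
            x = np.concatenate([np.full(keep.sum(), config.control_log_dose), x])
            y = np.concatenate([ctrl_y[keep], y])
        curves.append(CurveData(curve_id=str(cid), x=x, y=y))
    logger.info("read %d curves, excluded %d rows", len(curves), len(ledger))
    return curves, ledger


RESULT_COLUMNS = [
    "curve_id", "n", "pec50", "slope", "front", "back", "intercept",
    "sse_m0", "sse_m1", "rmse_m0", "f_value", "dfd", "p_value", "cfc",
    "f_adj", "relevance", "label",
]


def write_results(results: pd.DataFrame, config: PipelineConfig,
                  path: str | Path, header_extra: dict | None = None) -> Path:
    """Write the results TSV with a commented header block.

    The header records the config digest and seed so a result file can
    be traced back to its exact run settings.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# doseresp results\n# config_digest: {config.digest()}\n")
    buf.write(f"# seed: {config.seed}\n")
    for key, val in (header_extra or {}).items():
        buf.write(f"# {key}: {val}\n")
    results.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text(buf.getvalue())
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
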