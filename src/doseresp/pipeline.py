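"""Pipeline orchestration: read -> preprocess -> fit -> statistics ->
classification -> decoy FDR -> outputs.

The stages are plain functions over in-memory objects so they can be
driven from Python; :func:`run_pipeline` wires them together from a
TOML configuration for the command-line entry point.  A single global
seed fans out to stage-specific child seeds through a fixed
derivation, so decoy generation and null simulations are independently
reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoy_fdr import DecoyModel, compute_qvalues, estimate_variances, fdr_at_boundary, generate_decoys
from .fitting import FitBundle, FitOptions, fit_curves
from .io_config import RESULT_COLUMNS, PipelineConfig, read_table, write_results
from .models import CurveData, fold_change
from .relevance import Boundary, NotRegulatedRule, adjusted_f, classify_curve, relevance_score, CurveStatistics
from .significance import FCalibration, NullSimulationSpec, calibration_report, effective_dfd, f_value, p_value, simulate_null_curves

__all__ = [
    "RunManifest",
    "score_fits",
    "decoy_fdr_stage",
    "run_pipeline",
    "run_null_calibration",
    "qc_summary",
    "plot_outputs",
]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Bookkeeping of one pipeline run (counts must ledger-balance)."""

    config_digest: str = ""
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    global_fdr: float | None = None

    def to_text(self) -> str:
        lines = [f"config_digest: {self.config_digest}", f"seed: {self.seed}"]
        lines += [f"stage_seed.{k}: {v}" for k, v in self.stage_seeds.items()]
        lines += [f"count.{k}: {v}" for k, v in self.counts.items()]
        lines += [f"seconds.{k}: {v:.2f}" for k, v in self.timings.items()]
        if self.global_fdr is not None:
            lines.append(f"global_fdr_at_boundary: {self.global_fdr:.6g}")
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


def stage_seed(seed: int, stream: int) -> int:
    """Deterministic per-stage child seed (< 2**31) from the global seed."""
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def score_fits(
    fits: list[FitBundle],
    boundary: Boundary,
    calib: FCalibration | None = None,
    fc_mode: str = "range",
    not_rule: NotRegulatedRule = NotRegulatedRule(),
) -> pd.DataFrame:
    """Significance, relevance and class label for every fitted curve."""
    calib = calib or boundary.calib
    rows = []
    for fb in fits:
        F = f_value(fb.sse_m0, fb.sse_m1, fb.n, k=int(calib.k))
        p = p_value(F, fb.n, calib)
        cfc = fold_change(fb.params, fb.x_min, fb.x_max, mode=fc_mode)
        s0 = boundary.s0_for_n(fb.n)
        fadj = adjusted_f(F, cfc, s0)
        rel = relevance_score(fadj, fb.n, calib)
        st = CurveStatistics(
            curve_id=fb.curve_id, f=F, dfd=effective_dfd(fb.n, int(calib.k)),
            p=p, cfc=cfc, f_adj=fadj, relevance=rel, n=fb.n,
        )
        st.label = classify_curve(st, fb, boundary, not_rule)
        rows.append(
            {
                "curve_id": fb.curve_id, "n": fb.n,
                "pec50": fb.params.pec50, "slope": fb.params.slope,
                "front": fb.params.front, "back": fb.params.back,
                "intercept": fb.mean_fit.intercept,
                "sse_m0": fb.sse_m0, "sse_m1": fb.sse_m1, "rmse_m0": fb.rmse_m0,
                "f_value": F, "dfd": st.dfd, "p_value": p, "cfc": cfc,
                "f_adj": fadj, "relevance": rel, "label": st.label,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def decoy_fdr_stage(
    fits: list[FitBundle],
    results: pd.DataFrame,
    decoy_x: np.ndarray,
    boundary: Boundary,
    n_decoys: int = 0,
    seed: int = 0,
    fit_options: FitOptions = FitOptions(),
    fc_mode: str = "range",
) -> tuple[pd.DataFrame, float, int]:
    """Add decoy-based q-values to a scored results table.

    Decoys are flat-truth curves with variances resampled from the
    targets' own residual variances, pushed through the identical fit
    and scoring stages.  Returns (results with q_value column, global
    FDR at the boundary, number of decoys used).
    """
    variances = estimate_variances(fits)
    n_decoys = n_decoys or len(fits)
    model = DecoyModel(variance_sample=variances, n_decoys=n_decoys, seed=seed)
    decoys = generate_decoys(model, decoy_x)
    decoy_fits, _ = fit_curves(decoys, options=fit_options)
    decoy_scores = score_fits(decoy_fits, boundary, fc_mode=fc_mode)["relevance"].to_numpy()
    target_scores = results["relevance"].to_numpy()
    qtab = compute_qvalues(target_scores, decoy_scores)
    results = results.copy()
    idx = results.columns.get_loc("label")
    results.insert(idx, "q_value", qtab.q)
    global_fdr = fdr_at_boundary(target_scores, decoy_scores, boundary.relevance_threshold)
    return results, global_fdr, n_decoys


def run_pipeline(
    config: PipelineConfig,
    fdr: bool | None = None,
    random_n: int | None = None,
    plot: bool | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Run the full analysis described by a configuration.

    Deterministic given (config, seed).  Returns the results table and
    the run manifest; results and manifest are also written to the
    configured output paths.
    """
    if seed is not None:
        config.seed = seed
    fdr = config.fdr_enabled if fdr is None else fdr
    manifest = RunManifest(config_digest=config.digest(), seed=config.seed)
    calib = FCalibration(dfn=config.dfn, loc=config.loc, scale=config.scale)
    boundary = Boundary(config.alpha, config.fc_lim, calib=calib)
    not_rule = NotRegulatedRule(
        rmse_limit=config.rmse_limit,
        intercept_log2=config.intercept_log2,
        not_p_min=config.not_p_min if config.not_p_min > 0 else None,
    )
    fit_options = FitOptions(
        objective=config.objective, min_points=config.min_points, n_polish=config.n_polish
    )

    if random_n:
        # flat-truth simulation mode: calibration check instead of data
        t0 = time.time()
        spec = NullSimulationSpec(
            n_curves=random_n, n_points=len(config.doses),
            x=config.doses_log10, seed=stage_seed(config.seed, 3),
        )
        curves = simulate_null_curves(spec)
        manifest.stage_seeds["random"] = spec.seed
        ledger = {}
        manifest.counts["input_rows"] = random_n
    else:
        t0 = time.time()
        curves, ledger = read_table(config.input_path, config)
        manifest.counts["input_rows"] = len(curves) + len(ledger)
    manifest.counts["excluded_rows"] = len(ledger)
    manifest.timings["read"] = time.time() - t0

    t0 = time.time()
    fits, skipped = fit_curves(curves, options=fit_options)
    for cid, reason in skipped:
        ledger[cid] = reason
    manifest.counts["fitted"] = len(fits)
    manifest.counts["excluded_rows"] = len(ledger)
    manifest.timings["fit"] = time.time() - t0

    t0 = time.time()
    results = score_fits(fits, boundary, calib, config.fc_mode, not_rule)
    manifest.timings["score"] = time.time() - t0
    for lab in ("up", "down", "not", "unclear"):
        manifest.counts[f"label_{lab}"] = int((results["label"] == lab).sum())

    if random_n:
        report = calibration_report(results["p_value"].to_numpy())
        manifest.counts["calibration_ks_x1e4"] = int(round(report["ks_distance"] * 1e4))
        for lev, frac in report["fraction_below"].items():
            manifest.counts[f"fraction_p_below_{lev}"] = round(frac, 5)

    if fdr:
        t0 = time.time()
        if not len(config.doses):
            raise ValueError("decoy generation needs the dose grid in the config")
        ctrl = [config.control_log_dose] * len(config.control_columns)
        decoy_x = np.concatenate([ctrl, config.doses_log10])
        fdr_seed = stage_seed(config.seed, 7)
        manifest.stage_seeds["fdr"] = fdr_seed
        results, global_fdr, n_decoys = decoy_fdr_stage(
            fits, results, decoy_x, boundary,
            n_decoys=config.n_decoys, seed=fdr_seed,
            fit_options=fit_options, fc_mode=config.fc_mode,
        )
        manifest.global_fdr = global_fdr
        manifest.counts["decoys"] = n_decoys
        manifest.timings["fdr"] = time.time() - t0

    if config.output_path:
        write_results(results, config, config.output_path,
                      header_extra={"n_curves": len(results)})
        Path(str(config.output_path) + ".log").write_text(
            manifest.to_text()
            + "".join(f"excluded: {cid}: {why}\n" for cid, why in sorted(ledger.items()))
        )
    if plot and config.plot_dir:
        plot_outputs(results, boundary, config.plot_dir)
    return results, manifest


def run_null_calibration(
    n_curves: int,
    n_points: int = 10,
    seed: int = 0,
    variance_source: np.ndarray | None = None,
    calib: FCalibration | None = None,
    fit_options: FitOptions = FitOptions(),
) -> tuple[pd.DataFrame, dict]:
    """Simulate flat-truth curves, fit them, and report p-value calibration."""
    calib = calib or FCalibration()
    spec = NullSimulationSpec(
        n_curves=n_curves, n_points=n_points,
        variance_source=variance_source, seed=seed,
    )
    curves = simulate_null_curves(spec)
    fits, _ = fit_curves(curves, options=fit_options)
    boundary = Boundary(0.05, 0.0, calib=calib)
    results = score_fits(fits, boundary, calib)
    report = calibration_report(results["p_value"].to_numpy())
    return results, report


def qc_summary(fits: list[FitBundle], curves: list[CurveData]) -> pd.DataFrame:
    """Per-dose-column residual summary across all curves.

    Reports each response column's median residual (bias) and median
    absolute residual; flags columns whose median absolute residual
    exceeds twice the across-column median.  Flagging is suppressed
    with fewer than two curves (insufficient evidence).
    """
    from .models import loglogistic_eval

    by_id = {c.curve_id: c for c in curves}
    res_by_pos: dict[int, list[float]] = {}
    for fb in fits:
        c = by_id[fb.curve_id]
        r = c.y - loglogistic_eval(fb.params, c.x)
        for pos, val in enumerate(r):
            res_by_pos.setdefault(pos, []).append(float(val))
    rows = []
    for pos in sorted(res_by_pos):
        arr = np.asarray(res_by_pos[pos])
        rows.append({
            "column_index": pos,
            "median_residual": float(np.median(arr)),
            "median_abs_residual": float(np.median(np.abs(arr))),
        })
    out = pd.DataFrame(rows)
    ref = float(np.median(out["median_abs_residual"]))
    if len(fits) >= 2 and ref > 0:
        out["flagged"] = out["median_abs_residual"] > 2.0 * ref
    else:
        out["flagged"] = False
    return out


def plot_outputs(results: pd.DataFrame, boundary: Boundary, out_dir: str | Path,
                 max_curve_plots: int = 0, fits=None, curves=None) -> list[Path]:
    """Static diagnostic plots: volcano (p and relevance axes) and a
    pEC50 histogram of regulated curves; optional per-curve fit plots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .models import loglogistic_eval

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    reg = results["label"].isin(["up", "down"])
    n_ref = int(results["n"].mode().iat[0]) if len(results) else 10
    s0 = boundary.s0_for_n(n_ref)

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    logp = -np.log10(np.clip(results["p_value"], 1e-300, 1.0))
    axes[0].scatter(results["cfc"], logp, s=6, c=np.where(reg, "crimson", "grey"), alpha=0.6)
    # hyperbolic boundary in p-space: points whose relevance equals the threshold
    if s0 > 0:
        cfc_line = np.linspace(boundary.fc_asymptote * 1.0001, max(2.5, boundary.fc_asymptote * 4), 400)
        from scipy import stats as _st
        from .significance import effective_dfd as _dfd
        qthr = _st.f.ppf(1 - boundary.alpha_asymptote, boundary.calib.dfn,
                         _dfd(n_ref), loc=boundary.calib.loc)
        inv = 1.0 / np.sqrt(qthr) - s0 / cfc_line
        with np.errstate(divide="ignore"):
            f_line = np.where(inv > 0, 1.0 / inv**2, np.inf)
        p_line = _st.f.sf(f_line, boundary.calib.dfn, _dfd(n_ref), loc=boundary.calib.loc)
        ok = np.isfinite(f_line)
        for sign in (1, -1):
            axes[0].plot(sign * cfc_line[ok], -np.log10(np.clip(p_line[ok], 1e-300, 1)),
                         "k--", lw=1)
    axes[0].set_xlabel("curve fold change (log2)")
    axes[0].set_ylabel("-log10 p")
    axes[1].scatter(results["cfc"], results["relevance"], s=6,
                    c=np.where(reg, "crimson", "grey"), alpha=0.6)
    axes[1].axhline(boundary.relevance_threshold, color="k", ls="--", lw=1)
    axes[1].set_xlabel("curve fold change (log2)")
    axes[1].set_ylabel("relevance score")
    fig.tight_layout()
    p1 = out_dir / "volcano.png"
    fig.savefig(p1, dpi=150)
    plt.close(fig)
    written.append(p1)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(results.loc[reg, "pec50"].dropna(), bins=30, color="steelblue")
    ax.set_xlabel("pEC50 of regulated curves")
    ax.set_ylabel("count")
    fig.tight_layout()
    p2 = out_dir / "pec50_hist.png"
    fig.savefig(p2, dpi=150)
    plt.close(fig)
    written.append(p2)

    if max_curve_plots and fits and curves:
        by_id = {c.curve_id: c for c in curves}
        for fb in fits[:max_curve_plots]:
            c = by_id[fb.curve_id]
            xg = np.linspace(c.x[0], c.x[-1], 200)
            fig, ax = plt.subplots(figsize=(4.5, 3.5))
            ax.plot(c.x, c.y, "o", ms=4)
            ax.plot(xg, loglogistic_eval(fb.params, xg), "-", lw=1.5)
            ax.set_xlabel("log10 dose (M)")
            ax.set_ylabel("response (ratio)")
            ax.set_title(fb.curve_id, fontsize=9)
            fig.tight_layout()
            pc = out_dir / f"curve_{fb.curve_id}.png"
            fig.savefig(pc, dpi=120)
            plt.close(fig)
            written.append(pc)
    return written
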