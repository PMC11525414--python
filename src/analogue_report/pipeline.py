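"""End-to-end analysis over trial-table directories.

Stages mirror the analysis of a combined analogue-report / 2-AFC colour
experiment: non-parametric descriptives (cosine dissimilarity),
contamination-model fits per observer and condition, synchronous Gaussian
fits with κ-equivalents, 2-AFC psychometric fits, and the motor-noise
variance decomposition across wheel physical sizes. Group-level inference
(Bayesian ANOVA etc.) is deliberately excluded — the tidy per-observer
tables this module emits are the input any external inference tool needs.

All outputs are pure functions of (input tables, config); reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .afc import fit_afc_async, fit_afc_sync, pcorr_async, pcorr_sync
from .circular import circular_sd, cosine_dissimilarity, sigma_to_kappa
from .config import config_hash, default_config
from .errors import InsufficientDataError, SchemaError
from .mixture import contamination_pdf, fit_contamination, fit_sync_gaussian, response_errors
from .motor import angular_sd_from_motor, estimate_motor_variance

logger = logging.getLogger("analogue_report")

ANALOGUE_COLUMNS = ["observer", "session", "task", "timing", "set_size",
                    "delay_ms", "chroma_radius", "wheel_radius_dva",
                    "target_rad", "response_rad"]
AFC_COLUMNS = ["observer", "session", "timing", "set_size", "delay_ms",
               "chroma_radius", "target_rad", "delta_rad", "correct"]

ANALOGUE_KEYS = ["timing", "set_size", "delay_ms", "chroma_radius",
                 "wheel_radius_dva"]
AFC_KEYS = ["timing", "set_size", "delay_ms", "chroma_radius"]

TYPICAL_WHEEL_RADIUS_DVA = 8.2  # widely used wheel size, for context


def validate_table(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")
    for col in ("target_rad", "response_rad", "delta_rad"):
        if col in columns and not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"{name}: column {col} contains non-finite values")


def read_analogue_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df, ANALOGUE_COLUMNS, str(path))
    return df


def read_afc_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df, AFC_COLUMNS, str(path))
    return df


@dataclass
class AnalysisReport:
    """Tidy per-observer results plus cohort-level motor summary."""

    descriptives: pd.DataFrame
    analogue_fits: pd.DataFrame
    afc_fits: pd.DataFrame
    motor: pd.DataFrame
    motor_summary: dict
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_descriptive_rows": int(len(self.descriptives)),
            "n_analogue_fits": int(len(self.analogue_fits)),
            "n_afc_fits": int(len(self.afc_fits)),
            "motor_summary": self.motor_summary,
        }


def analogue_descriptives(analogue: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for keys, grp in analogue.groupby(["observer"] + ANALOGUE_KEYS, sort=True):
        errors = response_errors(grp)
        rec = dict(zip(["observer"] + ANALOGUE_KEYS, keys))
        rec.update(n_trials=len(grp),
                   cosine_dissimilarity=cosine_dissimilarity(errors),
                   circular_sd=circular_sd(errors))
        rows.append(rec)
    return pd.DataFrame(rows)


def fit_analogue_tables(analogue: pd.DataFrame, min_trials: int = 10) -> pd.DataFrame:
    """Contamination fit per observer × condition; synchronous conditions
    additionally get the Gaussian (σ_y, σ_t) treatment with κ-equivalents."""
    rows = []
    for keys, grp in analogue.groupby(["observer"] + ANALOGUE_KEYS, sort=True):
        rec = dict(zip(["observer"] + ANALOGUE_KEYS, keys))
        try:
            fit = fit_contamination(grp, min_trials=min_trials)
        except InsufficientDataError as exc:
            logger.warning("skipping %s: %s", keys, exc)
            continue
        rec.update(model="contamination", kappa_t=fit.kappa_t, alpha=fit.alpha,
                   loglik=fit.loglik, n_trials=fit.n_trials,
                   at_bound=fit.at_bound)
        if rec["timing"] == "synchronous":
            g = fit_sync_gaussian(grp)
            rec.update(sigma_y=g.sigma_y, sigma_t=g.sigma_t,
                       kappa_equiv=(sigma_to_kappa(g.sigma_t)
                                    if g.sigma_t > 0 else np.inf))
        rows.append(rec)
    return pd.DataFrame(rows)


def fit_afc_tables(afc: pd.DataFrame, min_trials: int = 20,
                   min_levels: int = 5) -> pd.DataFrame:
    rows = []
    for keys, grp in afc.groupby(["observer"] + AFC_KEYS, sort=True):
        rec = dict(zip(["observer"] + AFC_KEYS, keys))
        try:
            if rec["timing"] == "asynchronous":
                fit = fit_afc_async(grp, min_trials=min_trials,
                                    min_levels=min_levels)
                rec.update(model="afc_async", kappa_t=fit.kappa_t,
                           alpha=fit.alpha, loglik=fit.loglik,
                           n_trials=fit.n_trials, at_bound=fit.at_bound)
            else:
                fit = fit_afc_sync(grp, min_trials=min_trials,
                                   min_levels=min_levels)
                rec.update(model="afc_sync", sigma_t=fit.sigma_t,
                           kappa_equiv=sigma_to_kappa(fit.sigma_t),
                           loglik=fit.loglik, n_trials=fit.n_trials,
                           at_bound=fit.at_bound)
        except InsufficientDataError as exc:
            logger.warning("skipping %s: %s", keys, exc)
            continue
        rows.append(rec)
    return pd.DataFrame(rows)


def motor_decomposition(analogue: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-observer, per-condition motor estimates, then the group summary.

    Uses every condition cell observed on both the smallest and largest
    wheel; angular variance is the squared circular SD of the errors.
    """
    radii = sorted(analogue["wheel_radius_dva"].unique())
    if len(radii) < 2:
        raise InsufficientDataError(
            "motor_decomposition: need trials on at least two wheel radii")
    r_small, r_large = float(radii[0]), float(radii[-1])
    keys = ["observer", "timing", "set_size", "delay_ms", "chroma_radius"]
    rows = []
    for key_vals, grp in analogue.groupby(keys, sort=True):
        have = set(grp["wheel_radius_dva"].unique())
        if not {r_small, r_large} <= have:
            continue
        var = {}
        for r in (r_small, r_large):
            err = response_errors(grp[grp["wheel_radius_dva"] == r])
            var[r] = circular_sd(err) ** 2
        est = estimate_motor_variance(var[r_small], var[r_large],
                                      r_small, r_large)
        rec = dict(zip(keys, key_vals))
        rec.update(sigma2_small=est.sigma2_small, sigma2_large=est.sigma2_large,
                   sigma2_motor=est.sigma2_motor,
                   sigma_motor_dva=est.sigma_motor_dva,
                   negative_variance=est.negative_variance)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        raise InsufficientDataError(
            "motor_decomposition: no condition observed on both wheels")
    mean_var = float(table["sigma2_motor"].mean())
    summary = {
        "n_estimates": int(len(table)),
        "mean_sigma2_motor": mean_var,
        "n_negative": int(table["negative_variance"].sum()),
        "group_sigma_motor_dva": float(np.sqrt(mean_var)) if mean_var >= 0 else None,
        "R_small_dva": r_small,
        "R_large_dva": r_large,
    }
    if mean_var > 0:
        sd = float(np.sqrt(mean_var))
        summary["angular_sd_deg_small_wheel"] = angular_sd_from_motor(sd, r_small)
        summary["angular_sd_deg_large_wheel"] = angular_sd_from_motor(sd, r_large)
        summary["angular_sd_deg_typical_wheel"] = angular_sd_from_motor(
            sd, TYPICAL_WHEEL_RADIUS_DVA)
    return table, summary


def run_pipeline(input_dir, config: dict | None = None,
                 output_dir=None, seed: int = 0) -> AnalysisReport:
    """Run every analysis stage over ``input_dir`` and write the report.

    Expects ``analogue_trials.csv`` and ``afc_trials.csv`` in
    ``input_dir`` (schemas in this module). Writes per-stage CSVs, a JSON
    report and a log into ``output_dir`` when given.
    """
    cfg = config or default_config()
    input_dir = Path(input_dir)
    analogue = read_analogue_csv(input_dir / "analogue_trials.csv")
    afc_path = input_dir / "afc_trials.csv"
    afc = read_afc_csv(afc_path) if afc_path.exists() else pd.DataFrame(columns=AFC_COLUMNS)

    timings = {}
    t0 = time.perf_counter()
    descr = analogue_descriptives(analogue)
    timings["descriptives_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    analogue_fits = fit_analogue_tables(
        analogue, min_trials=cfg["fit"]["min_analogue_trials"])
    timings["analogue_fits_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    if len(afc):
        afc_fits = fit_afc_tables(afc, min_trials=cfg["fit"]["min_afc_trials"],
                                  min_levels=cfg["fit"]["min_delta_levels"])
    else:
        afc_fits = pd.DataFrame()
    timings["afc_fits_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    try:
        motor, motor_summary = motor_decomposition(analogue)
    except InsufficientDataError as exc:
        logger.warning("motor decomposition skipped: %s", exc)
        motor, motor_summary = pd.DataFrame(), {"skipped": str(exc)}
    timings["motor_s"] = round(time.perf_counter() - t0, 3)

    report = AnalysisReport(
        descriptives=descr, analogue_fits=analogue_fits, afc_fits=afc_fits,
        motor=motor, motor_summary=motor_summary,
        provenance={"config_hash": config_hash(cfg), "seed": int(seed),
                    "version": _pkg_version, "input_dir": str(input_dir),
                    "stage_timings": timings})
    if output_dir is not None:
        write_report(report, output_dir)
    return report


def write_report(report: AnalysisReport, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    report.analogue_fits.to_csv(out / "analogue_fits.csv", index=False)
    report.afc_fits.to_csv(out / "afc_fits.csv", index=False)
    report.motor.to_csv(out / "motor_estimates.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(out / "pipeline.log", "w") as fh:
        for stage, secs in report.provenance["stage_timings"].items():
            fh.write(f"{stage}: {secs}\n")


def make_figure_tables(analogue: pd.DataFrame, afc: pd.DataFrame,
                       analogue_fits: pd.DataFrame, afc_fits: pd.DataFrame,
                       n_error_bins: int = 36, n_afc_bins: int = 12,
                       n_curve: int = 181) -> dict:
    """Binned summaries and model curves, as plotted-figure source tables.

    Returns ``error_hist`` (per-condition binned error masses with the
    mean contamination-fit density at bin centres), ``afc_bins`` (2-AFC
    accuracy in ``n_afc_bins`` linear bins of |δ| with per-bin counts) and
    ``afc_curves`` (fitted link functions on a dense |δ| grid).
    """
    out = {}
    edges = np.linspace(-np.pi, np.pi, n_error_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    hist_rows = []
    for keys, grp in analogue.groupby(ANALOGUE_KEYS, sort=True):
        if len(grp) == 0:
            continue
        errors = response_errors(grp)
        mass, _ = np.histogram(errors, bins=edges)
        mass = mass / mass.sum()
        cond = dict(zip(ANALOGUE_KEYS, keys))
        sel = analogue_fits
        for k, v in cond.items():
            sel = sel[sel[k] == v]
        dens = np.full_like(centres, np.nan)
        if len(sel):
            dens = np.mean([contamination_pdf(centres, 0.0, r.kappa_t, r.alpha)
                            for r in sel.itertuples()], axis=0)
        for c, m, f in zip(centres, mass, dens):
            hist_rows.append({**cond, "bin_centre_rad": c, "mass": m,
                              "model_density": f})
    out["error_hist"] = pd.DataFrame(hist_rows)

    afc_rows, curve_rows = [], []
    bin_edges = np.linspace(0.0, np.pi, n_afc_bins + 1)
    dense = np.linspace(0.0, np.pi, n_curve)
    for keys, grp in afc.groupby(AFC_KEYS, sort=True):
        if len(grp) == 0:
            continue
        cond = dict(zip(AFC_KEYS, keys))
        d = np.abs(grp["delta_rad"].to_numpy(dtype=float))
        corr = grp["correct"].to_numpy().astype(float)
        idx = np.clip(np.digitize(d, bin_edges) - 1, 0, n_afc_bins - 1)
        for b in range(n_afc_bins):
            in_bin = idx == b
            if not in_bin.any():
                continue
            afc_rows.append({**cond,
                             "bin_centre_rad": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                             "accuracy": float(corr[in_bin].mean()),
                             "n_trials": int(in_bin.sum())})
        sel = afc_fits
        for k, v in cond.items():
            sel = sel[sel[k] == v]
        if len(sel):
            if cond["timing"] == "asynchronous":
                curves = [pcorr_async(dense, r.kappa_t, r.alpha)
                          for r in sel.itertuples()]
            else:
                curves = [pcorr_sync(dense, r.sigma_t) for r in sel.itertuples()]
            mean_curve = np.mean(curves, axis=0)
            for x, p in zip(dense, mean_curve):
                curve_rows.append({**cond, "d_rad": x, "p_correct": p})
    out["afc_bins"] = pd.DataFrame(afc_rows)
    out["afc_curves"] = pd.DataFrame(curve_rows)
    return out
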