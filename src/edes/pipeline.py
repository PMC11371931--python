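"""Cohort-scale driver: calibrate every response in both modes, profile
identifiability, and assemble the plasma-vs-CGM comparison report.

The comparison report mirrors the study workflow: per-mode MSE summaries,
residuals grouped by nominal design time, two-sample Kolmogorov-Smirnov
tests and Spearman rank correlations between the modes' parameter
estimates, boundary-estimate bookkeeping (fits with k6 pinned to the upper
search bound are excluded from the parameter-distribution and
indicator-correlation analyses, not from MSE summaries), unidentifiable
model counts, and the Spearman table of estimates against metabolic
indicators with a p < 0.05 significance flag.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (CalibrationConfig, CalibrationResult,
                          UnusableResponseError, build_observations,
                          tiktak_calibrate)
from .identifiability import identifiability_report
from .params import FixedParameters

__all__ = [
    "run_cohort",
    "spearman",
    "ks_two_sample",
    "build_report",
    "ComparisonReport",
    "CohortResults",
]

logger = logging.getLogger(__name__)

#: estimates within this absolute distance of the k6 upper search bound are
#: treated as boundary fits in the report analyses
MODES = ("plasma", "cgm")


# ----------------------------------------------------------------------
# statistics


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks are tie-corrected.  For n <= 7 the p-value is computed by exact
    permutation enumeration of one margin (matching a brute-force oracle);
    for larger n the asymptotic approximation is used.  Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("spearman needs at least 3 paired finite samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 7:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(_rank_corr(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            count += abs(r) >= observed - 1e-12
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


def _rank_corr(rx, ry) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D = sup|ECDF_a - ECDF_b|
    with the asymptotic two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# cohort runs


@dataclass
class CohortResults:
    """Per-response x mode results store."""

    table: pd.DataFrame                 # one row per response x mode
    residuals: pd.DataFrame             # stacked residual tables
    fits: dict = field(default_factory=dict)   # (key, mode) -> CalibrationResult
    reports: dict = field(default_factory=dict)  # (key, mode) -> report record


def run_cohort(responses, fixed: FixedParameters | None = None,
               modes=MODES, configs: dict | None = None,
               seed: int = 0,
               include_identifiability: bool = True) -> CohortResults:
    """Calibrate (and optionally profile) every response in every mode.

    ``configs`` maps mode -> CalibrationConfig; per-response seeds are
    derived deterministically from ``seed``.  Individual failures are
    logged and recorded with ``success=False``; they never abort the run.
    """
    if fixed is None:
        fixed = FixedParameters()
    if configs is None:
        configs = {}
    rows, resid_frames = [], []
    fits, reports = {}, {}
    mode_offset = {"plasma": 0, "cgm": 1}
    for j, resp in enumerate(responses):
        for mode in modes:
            config = configs.get(mode, CalibrationConfig(mode=mode))
            config = config.replace(
                mode=mode,
                seed=(seed * 100003 + j * 7 + mode_offset[mode]) % (2 ** 31))
            row = {"subject_id": resp.subject_id, "visit": resp.visit,
                   "key": resp.key, "mode": mode}
            try:
                obs = build_observations(resp, mode)
                ctx = resp.context(mode)
                fit = tiktak_calibrate(obs, config, fixed, ctx)
            except (UnusableResponseError, ValueError) as exc:
                logger.warning("%s/%s: unusable (%s)", resp.key, mode, exc)
                row.update({"success": False, "error": str(exc)})
                rows.append(row)
                continue
            fits[(resp.key, mode)] = fit
            row.update(fit.to_record())
            if fit.success:
                rt = fit.residual_table.copy()
                rt["key"], rt["mode"] = resp.key, mode
                resid_frames.append(rt)
                if include_identifiability:
                    rep, curves = identifiability_report(
                        fit, obs, fixed, ctx, config=config)
                    reports[(resp.key, mode)] = rep
                    row["model_identifiable"] = rep.model_identifiable
                    row["unidentifiable_parameters"] = ",".join(
                        rep.unidentifiable_parameters)
            rows.append(row)
    table = pd.DataFrame(rows)
    residuals = (pd.concat(resid_frames, ignore_index=True)
                 if resid_frames else pd.DataFrame())
    return CohortResults(table=table, residuals=residuals,
                         fits=fits, reports=reports)


# ----------------------------------------------------------------------
# comparison report


@dataclass
class ComparisonReport:
    mse_summary: dict
    residual_summary: pd.DataFrame
    parameter_ks: dict          # param -> {D, p}
    parameter_spearman: dict    # param -> {rho, p}
    boundary_counts: dict       # mode -> count of k6-boundary fits
    excluded_models: list       # keys excluded for boundary k6
    unidentifiable_counts: dict
    indicator_correlations: pd.DataFrame
    mse_threshold: float

    def to_record(self) -> dict:
        return {
            "mse_summary": self.mse_summary,
            "parameter_ks": self.parameter_ks,
            "parameter_spearman": self.parameter_spearman,
            "boundary_counts": self.boundary_counts,
            "excluded_models": self.excluded_models,
            "unidentifiable_counts": self.unidentifiable_counts,
            "mse_threshold": self.mse_threshold,
            "indicator_correlations":
                self.indicator_correlations.to_dict(orient="records"),
            "residual_summary":
                self.residual_summary.to_dict(orient="records"),
        }


INDICATOR_COLUMNS = ("misi", "hiri", "homa_ir", "matsuda", "auc30_glu",
                     "homa_beta", "auc30_ins", "insulinogenic_index",
                     "disposition_index")


def build_report(results: CohortResults,
                 indicators: pd.DataFrame | None = None,
                 mse_threshold: float = 1.5) -> ComparisonReport:
    """Assemble the plasma-vs-CGM comparison report from a results store."""
    df = results.table
    ok = df[df.get("success", True) == True]  # noqa: E712

    # --- MSE distributions per mode/observable ---
    mse_summary = {}
    for mode in MODES:
        sub = ok[ok["mode"] == mode]
        for obs_name in ("glucose", "insulin"):
            col = f"mse_{obs_name}"
            if col not in sub or sub[col].dropna().empty:
                continue
            v = sub[col].dropna().to_numpy()
            mse_summary[f"{mode}_{obs_name}"] = {
                "median": float(np.median(v)),
                "mean": float(np.mean(v)),
                "n": int(v.size),
                "n_above_threshold": int((v > mse_threshold).sum()),
            }

    # --- residuals grouped by nominal design time ---
    if len(results.residuals):
        residual_summary = (results.residuals
                            .groupby(["mode", "observable", "time_min"])
                            ["residual"]
                            .agg(["mean", "median", "std", "count"])
                            .reset_index())
    else:
        residual_summary = pd.DataFrame()

    # --- boundary-k6 bookkeeping ---
    boundary = ok[ok.get("boundary_k6", False) == True]  # noqa: E712
    excluded_keys = sorted(set(boundary["key"])) if len(boundary) else []
    boundary_counts = {m: int((boundary["mode"] == m).sum()) for m in MODES}

    # cross-mode comparisons on paired, non-boundary-excluded responses
    wide = {}
    for mode in MODES:
        sub = ok[ok["mode"] == mode].set_index("key")
        wide[mode] = sub
    paired_keys = [k for k in wide["plasma"].index
                   if k in wide["cgm"].index]
    param_ks, param_rho = {}, {}
    analysis_keys = [k for k in paired_keys if k not in excluded_keys]
    for param in ("k1", "k5", "k6"):
        a = wide["plasma"].loc[analysis_keys, param].astype(float)
        b = wide["cgm"].loc[analysis_keys, param].astype(float)
        if len(analysis_keys) >= 3:
            d, pk = ks_two_sample(a, b)
            rho, pr = spearman(a, b)
            param_ks[param] = {"D": d, "p": pk}
            param_rho[param] = {"rho": rho, "p": pr}

    # --- unidentifiable counts per mode ---
    unident = {}
    if "model_identifiable" in ok.columns:
        for mode in MODES:
            sub = ok[ok["mode"] == mode]["model_identifiable"].dropna()
            unident[mode] = int((~sub.astype(bool)).sum())

    # --- estimates vs indicators (boundary-k6 fits excluded) ---
    corr_rows = []
    if indicators is not None and len(indicators):
        ind = indicators.copy()
        ind["key"] = ind["subject_id"].astype(str) + "_" + ind["visit"].astype(str)
        ind = ind.set_index("key")
        for indicator in INDICATOR_COLUMNS:
            row = {"indicator": indicator}
            for param in ("k1", "k5", "k6"):
                for mode in MODES:
                    keys = [k for k in analysis_keys if k in ind.index]
                    if indicator not in ind.columns or len(keys) < 3:
                        row[f"{param}_{mode}"] = float("nan")
                        row[f"{param}_{mode}_p"] = float("nan")
                        continue
                    est = wide[mode].loc[keys, param].astype(float)
                    val = ind.loc[keys, indicator].astype(float)
                    try:
                        rho, p = spearman(est, val)
                    except ValueError:
                        rho, p = float("nan"), float("nan")
                    row[f"{param}_{mode}"] = rho
                    row[f"{param}_{mode}_p"] = p
                    row[f"{param}_{mode}_significant"] = bool(p < 0.05) \
                        if np.isfinite(p) else False
            corr_rows.append(row)
    indicator_correlations = pd.DataFrame(corr_rows)

    return ComparisonReport(
        mse_summary=mse_summary,
        residual_summary=residual_summary,
        parameter_ks=param_ks,
        parameter_spearman=param_rho,
        boundary_counts=boundary_counts,
        excluded_models=excluded_keys,
        unidentifiable_counts=unident,
        indicator_correlations=indicator_correlations,
        mse_threshold=mse_threshold,
    )
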