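"""Fasting- and OGTT-derived indicators of insulin sensitivity and
beta-cell function.

All indices are computed from the 7-point plasma glucose (mmol/L) and
insulin (mU/L) response.  Unit conventions differ between the published
formulas -- the HOMA family works in mmol/L x mU/L, whereas the Matsuda
composite index, MISI and HIRI are defined on mg/dL glucose -- and those
conversions are localized inside this module.  An index whose required
samples are missing (or whose ratio degenerates) is reported as NaN with a
logged reason, never as a silent zero.

Implemented indices
-------------------
HOMA-IR        G0 * I0 / 22.5                       (fasting insulin resistance)
HOMA-beta      20 * I0 / (G0 - 3.5)                 (fasting beta-cell function)
Matsuda        10000 / sqrt(G0 * I0 * Gmean * Imean), glucose in mg/dL
AUC30_glu/ins  trapezoidal area 0-30 min            (early-phase exposure)
Insulinogenic  (I30 - I0) / (G30 - G0)              (early-phase secretion)
HIRI           AUC30_glu[mg/dL*min] * AUC30_ins     (hepatic insulin resistance)
MISI           post-peak glucose decline slope [mg/dL/min] / mean insulin
Disposition    insulinogenic index * Matsuda        (secretion adjusted for
                                                     sensitivity)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data import SubjectResponse

__all__ = ["IndicatorSet", "auc_segment", "compute_indicators",
           "cohort_indicators", "MGDL_PER_MMOL"]

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L of glucose (molar mass 180.156 g/mol)
MGDL_PER_MMOL = 18.0156


@dataclass(frozen=True)
class IndicatorSet:
    """Metabolic indicators of one response; NaN marks a value whose
    inputs were missing or degenerate."""

    matsuda: float
    homa_ir: float
    homa_beta: float
    misi: float
    hiri: float
    auc30_glu: float          # mmol/L * min
    auc30_ins: float          # mU/L * min
    insulinogenic_index: float
    disposition_index: float

    def to_dict(self) -> dict:
        return asdict(self)


def auc_segment(times, values, t_start: float, t_end: float) -> float:
    """Trapezoidal area under ``values`` over [t_start, t_end].

    Samples at both endpoints must be present (non-NaN); interior NaN
    samples are dropped.  Returns NaN when an endpoint sample is missing.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= t_start - 1e-9) & (times <= t_end + 1e-9)
    t, y = times[mask], values[mask]
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if t.size < 2 or not (np.isclose(t[0], t_start)
                          and np.isclose(t[-1], t_end)):
        return float("nan")
    return float(np.trapezoid(y, t))


def _sample_at(times, values, t):
    idx = np.flatnonzero(np.isclose(times, t))
    if idx.size == 0 or np.isnan(values[idx[0]]):
        return float("nan")
    return float(values[idx[0]])


def compute_indicators(response: SubjectResponse) -> IndicatorSet:
    """All indices of one plasma OGTT response (missing -> NaN)."""
    t = response.ogtt_times
    glu = response.plasma_glucose
    ins = response.plasma_insulin
    key = response.key

    g0 = _sample_at(t, glu, 0.0)
    i0 = _sample_at(t, ins, 0.0)
    g30 = _sample_at(t, glu, 30.0)
    i30 = _sample_at(t, ins, 30.0)

    nan = float("nan")

    # --- fasting indices ---
    homa_ir = g0 * i0 / 22.5 if np.isfinite(g0 * i0) else nan
    if np.isfinite(g0) and np.isfinite(i0):
        if g0 == 3.5:
            logger.info("%s: HOMA-beta degenerate (G0 = 3.5 mmol/L)", key)
            homa_beta = nan
        else:
            homa_beta = 20.0 * i0 / (g0 - 3.5)
    else:
        homa_beta = nan

    # --- whole-OGTT composite (Matsuda), glucose in mg/dL ---
    both = ~np.isnan(glu) & ~np.isnan(ins)
    if np.isfinite(g0) and np.isfinite(i0) and both.sum() >= 3:
        g_mean = float(np.mean(glu[both])) * MGDL_PER_MMOL
        i_mean = float(np.mean(ins[both]))
        matsuda = 10000.0 / np.sqrt(g0 * MGDL_PER_MMOL * i0 * g_mean * i_mean)
    else:
        matsuda = nan

    # --- early-phase exposure and secretion ---
    auc30_glu = auc_segment(t, glu, 0.0, 30.0)
    auc30_ins = auc_segment(t, ins, 0.0, 30.0)
    if np.isfinite(g30) and np.isfinite(i30) and np.isfinite(g0) \
            and np.isfinite(i0):
        if g30 == g0:
            logger.info("%s: insulinogenic index degenerate (G30 = G0)", key)
            insulinogenic = nan
        else:
            insulinogenic = (i30 - i0) / (g30 - g0)
    else:
        insulinogenic = nan
    hiri = (auc30_glu * MGDL_PER_MMOL * auc30_ins
            if np.isfinite(auc30_glu) and np.isfinite(auc30_ins) else nan)

    # --- muscle insulin sensitivity: post-peak decline / mean insulin ---
    misi = _misi(t, glu, ins, key)

    disposition = (insulinogenic * matsuda
                   if np.isfinite(insulinogenic) and np.isfinite(matsuda)
                   else nan)

    return IndicatorSet(
        matsuda=matsuda, homa_ir=homa_ir, homa_beta=homa_beta,
        misi=misi, hiri=hiri, auc30_glu=auc30_glu, auc30_ins=auc30_ins,
        insulinogenic_index=insulinogenic, disposition_index=disposition)


def _misi(t, glu, ins, key) -> float:
    """Slope of the glucose decline from peak to nadir (mg/dL/min),
    normalized by the mean insulin over the test; 0 for a flat response."""
    ok_g = ~np.isnan(glu)
    ok_i = ~np.isnan(ins)
    if ok_g.sum() < 3 or ok_i.sum() < 1:
        logger.info("%s: MISI not computable (too few samples)", key)
        return float("nan")
    tg, g = t[ok_g], glu[ok_g]
    i_mean = float(np.mean(ins[ok_i]))
    if i_mean <= 0:
        return float("nan")
    p = int(np.argmax(g))
    if p == g.size - 1:  # peak at the final sample: no decline phase
        return 0.0
    post_t, post_g = tg[p:], g[p:]
    n = int(np.argmin(post_g))
    if n == 0 or post_g[0] == post_g[n]:
        return 0.0
    slope = (post_g[0] - post_g[n]) / (post_t[n] - post_t[0])  # mmol/L/min
    return float(slope * MGDL_PER_MMOL / i_mean)


def cohort_indicators(responses) -> pd.DataFrame:
    """One row of indicator columns per response (NaN = missing)."""
    rows = []
    for r in responses:
        rec = {"subject_id": r.subject_id, "visit": r.visit}
        rec.update(compute_indicators(r).to_dict())
        rows.append(rec)
    return pd.DataFrame(rows)
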