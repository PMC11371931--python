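"""Subject responses and the CSV schemas of the cohort directory layout.

A cohort lives in a directory::

    context.csv                 subject_id, visit, body_mass_kg, dose_g
    ogtt/<subject>_<visit>.csv  time_min, plasma_glucose_mmol_per_L,
                                plasma_insulin_mU_per_L
    cgm/<subject>_<visit>.csv   time_min, interstitial_glucose_mmol_per_L
    truth.csv (synthetic only)  subject_id, visit, k1, k5, k6, tau_g

OGTT rows are aligned to the 7-point design grid on read; design times
without a row (or with an empty cell) become NaN so downstream exclusion
rules can count missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SubjectContext

__all__ = [
    "OGTT_DESIGN_TIMES",
    "CGM_DESIGN_TIMES",
    "SubjectResponse",
    "write_cohort",
    "read_cohort",
]

#: blood sampling grid of the 7-point oral glucose tolerance test (min)
OGTT_DESIGN_TIMES = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])

#: 5-min interstitial sensor grid spanning the test window (min)
CGM_DESIGN_TIMES = np.arange(0.0, 131.0, 5.0)


@dataclass
class SubjectResponse:
    """One person-visit's measured OGTT series, CGM trace and context."""

    subject_id: str
    visit: str
    ogtt_times: np.ndarray
    plasma_glucose: np.ndarray          # mmol/L, NaN = missing sample
    plasma_insulin: np.ndarray          # mU/L, NaN = missing sample
    cgm_times: np.ndarray | None        # min, None = no CGM trace
    cgm_glucose: np.ndarray | None      # mmol/L
    body_mass: float                    # kg
    glucose_dose: float = 75.0          # g

    def __post_init__(self):
        self.ogtt_times = np.asarray(self.ogtt_times, dtype=float)
        self.plasma_glucose = np.asarray(self.plasma_glucose, dtype=float)
        self.plasma_insulin = np.asarray(self.plasma_insulin, dtype=float)
        if self.cgm_times is not None:
            self.cgm_times = np.asarray(self.cgm_times, dtype=float)
            self.cgm_glucose = np.asarray(self.cgm_glucose, dtype=float)

    @property
    def key(self) -> str:
        return f"{self.subject_id}_{self.visit}"

    # --- missing-sample bookkeeping (a "sample" is one blood draw) ---

    @property
    def missing_plasma_mask(self) -> np.ndarray:
        return np.isnan(self.plasma_glucose) | np.isnan(self.plasma_insulin)

    @property
    def n_missing_plasma(self) -> int:
        return int(self.missing_plasma_mask.sum())

    def _has_time(self, t: float) -> bool:
        idx = np.flatnonzero(np.isclose(self.ogtt_times, t))
        return idx.size > 0 and not self.missing_plasma_mask[idx[0]]

    @property
    def has_baseline(self) -> bool:
        return self._has_time(0.0)

    @property
    def has_two_hour(self) -> bool:
        return self._has_time(120.0)

    @property
    def cgm_uniform_5min(self) -> bool:
        """True when the CGM grid spacing is uniformly 5 min."""
        if self.cgm_times is None or self.cgm_times.size < 2:
            return False
        return bool(np.allclose(np.diff(self.cgm_times), 5.0))

    def cgm_at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.cgm_times, t))
        if idx.size == 0:
            raise ValueError(f"no CGM sample at t={t} min")
        return float(self.cgm_glucose[idx[0]])

    # --- model inputs ---

    def context(self, mode: str = "plasma") -> SubjectContext:
        """Subject context with the mode-matched basal glucose input.

        The t = 0 sample of the fitted glucose channel is the model's basal
        glucose (plasma t = 0 in plasma mode, CGM t = 0 in cgm mode); basal
        insulin is always the plasma t = 0 insulin.
        """
        if not self.has_baseline:
            raise ValueError(f"{self.key}: missing baseline (t=0) sample")
        ib = float(self.plasma_insulin[0])
        if mode == "plasma":
            gb = float(self.plasma_glucose[0])
            return SubjectContext(self.body_mass, self.glucose_dose, gb, ib)
        if mode == "cgm":
            if self.cgm_times is None:
                raise ValueError(f"{self.key}: no CGM trace")
            gb = self.cgm_at(0.0)
            return SubjectContext(self.body_mass, self.glucose_dose, gb, ib,
                                  basal_interstitial_glucose=gb)
        raise ValueError(f"unknown mode {mode!r}")

    def replace(self, **kw) -> "SubjectResponse":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# cohort directory I/O


def write_cohort(directory, responses, truth: pd.DataFrame | None = None):
    """Write a cohort of responses in the standard directory layout."""
    directory = Path(directory)
    (directory / "ogtt").mkdir(parents=True, exist_ok=True)
    (directory / "cgm").mkdir(exist_ok=True)
    ctx_rows = []
    for r in responses:
        ctx_rows.append({"subject_id": r.subject_id, "visit": r.visit,
                         "body_mass_kg": r.body_mass, "dose_g": r.glucose_dose})
        ogtt = pd.DataFrame({
            "time_min": r.ogtt_times,
            "plasma_glucose_mmol_per_L": r.plasma_glucose,
            "plasma_insulin_mU_per_L": r.plasma_insulin,
        })
        # missing samples are absent rows, as in an export of measured data
        ogtt = ogtt.dropna(how="all",
                           subset=["plasma_glucose_mmol_per_L",
                                   "plasma_insulin_mU_per_L"])
        ogtt.to_csv(directory / "ogtt" / f"{r.key}.csv", index=False)
        if r.cgm_times is not None:
            cgm = pd.DataFrame({
                "time_min": r.cgm_times,
                "interstitial_glucose_mmol_per_L": r.cgm_glucose,
            })
            cgm.to_csv(directory / "cgm" / f"{r.key}.csv", index=False)
    pd.DataFrame(ctx_rows).to_csv(directory / "context.csv", index=False)
    if truth is not None:
        truth.to_csv(directory / "truth.csv", index=False)


def read_cohort(directory) -> list[SubjectResponse]:
    """Read a cohort directory back into :class:`SubjectResponse` objects."""
    directory = Path(directory)
    ctx = pd.read_csv(directory / "context.csv",
                      dtype={"subject_id": str, "visit": str})
    responses = []
    for row in ctx.itertuples(index=False):
        key = f"{row.subject_id}_{row.visit}"
        ogtt_path = directory / "ogtt" / f"{key}.csv"
        glu = np.full(OGTT_DESIGN_TIMES.size, np.nan)
        ins = np.full(OGTT_DESIGN_TIMES.size, np.nan)
        if ogtt_path.exists():
            df = pd.read_csv(ogtt_path)
            for t, g, i in zip(df["time_min"],
                               df["plasma_glucose_mmol_per_L"],
                               df["plasma_insulin_mU_per_L"]):
                j = np.flatnonzero(np.isclose(OGTT_DESIGN_TIMES, t))
                if j.size:
                    glu[j[0]], ins[j[0]] = g, i
        cgm_path = directory / "cgm" / f"{key}.csv"
        cgm_t = cgm_g = None
        if cgm_path.exists():
            cdf = pd.read_csv(cgm_path)
            cgm_t = cdf["time_min"].to_numpy(dtype=float)
            cgm_g = cdf["interstitial_glucose_mmol_per_L"].to_numpy(dtype=float)
        responses.append(SubjectResponse(
            subject_id=row.subject_id, visit=row.visit,
            ogtt_times=OGTT_DESIGN_TIMES.copy(),
            plasma_glucose=glu, plasma_insulin=ins,
            cgm_times=cgm_t, cgm_glucose=cgm_g,
            body_mass=float(row.body_mass_kg),
            glucose_dose=float(row.dose_g)))
    return responses


def read_truth(directory) -> pd.DataFrame | None:
    path = Path(directory) / "truth.csv"
    if not path.exists():
        return None
    return pd.read_csv(path, dtype={"subject_id": str, "visit": str})
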