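"""Synthetic cohorts of simultaneous OGTT plasma + CGM responses with known
ground-truth parameters.

Each synthetic subject is drawn from log-normal population distributions of
the estimable parameters and context variables, simulated through the ODE
model, sampled on the study designs (7-point OGTT blood draws; 5-min CGM
grid over a 130-min window) and then corrupted by a configurable
measurement-noise model: multiplicative assay noise on plasma glucose and
insulin, and proportional sensor error plus a per-trace additive bias on
CGM glucose.  Optional missingness and grid irregularities emulate the
data-cleaning situations the exclusion rules must handle.

The generator is fully reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (CGM_DESIGN_TIMES, OGTT_DESIGN_TIMES, SubjectResponse)
from .model_core import SimulationError, Trajectory, simulate
from .params import EstimableParameters, FixedParameters, SubjectContext

__all__ = [
    "LogNormalSpec",
    "NoiseModel",
    "CohortSpec",
    "SyntheticSubject",
    "sample_subject",
    "inject_missingness",
    "apply_exclusions",
    "generate_cohort",
    "cohort_truth",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal sampling distribution given by median and log-scale SD."""

    median: float
    sigma_log: float
    lower: float = 0.0       # truncation bounds applied by clipping
    upper: float = np.inf

    def draw(self, rng: np.random.Generator) -> float:
        v = self.median * np.exp(self.sigma_log * rng.standard_normal())
        return float(np.clip(v, self.lower, self.upper))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied after simulation.

    Plasma channels get multiplicative Gaussian noise (coefficient of
    variation); the CGM trace gets proportional error plus one additive
    bias per trace.  The bias has a positive mean: calibrated interstitial
    sensor readings run systematically above plasma glucose during an
    OGTT, on top of the diffusion lag.  Noisy values are truncated away
    from zero to keep concentrations positive.
    """

    plasma_glucose_cv: float = 0.02
    insulin_cv: float = 0.07
    cgm_proportional_cv: float = 0.05
    cgm_bias_mean: float = 0.3      # mmol/L, systematic sensor offset
    cgm_bias_sd: float = 0.2        # mmol/L, one draw per trace

    def __post_init__(self):
        for name in ("plasma_glucose_cv", "insulin_cv",
                     "cgm_proportional_cv", "cgm_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def apply_plasma(self, glucose, insulin, rng):
        g = glucose * (1.0 + self.plasma_glucose_cv
                       * rng.standard_normal(glucose.shape))
        i = insulin * (1.0 + self.insulin_cv
                       * rng.standard_normal(insulin.shape))
        return np.maximum(g, 1e-6), np.maximum(i, 1e-6)

    def apply_cgm(self, cgm, rng):
        bias = self.cgm_bias_mean + self.cgm_bias_sd * rng.standard_normal()
        y = cgm * (1.0 + self.cgm_proportional_cv
                   * rng.standard_normal(cgm.shape)) + bias
        return np.maximum(y, 1e-6)


def _default_distributions() -> dict:
    # centered on the population-scale default estimables; tau_g spread wide
    # enough that the upper quartile reaches ~8.5 min (near-zero lags in
    # field data appear as boundary fits rather than a log-normal tail)
    return {
        "k1": LogNormalSpec(0.015, 0.30, 1e-3, 0.1),
        "k5": LogNormalSpec(0.035, 0.50, 1e-4, 0.5),
        "k6": LogNormalSpec(0.8, 0.40, 0.01, 10.0),
        "tau_g": LogNormalSpec(2.5, 1.8, 1e-6, 30.0),
        "body_mass": LogNormalSpec(90.0, 0.12, 50.0, 160.0),
        "basal_glucose": LogNormalSpec(5.4, 0.08, 3.5, 8.0),
        "basal_insulin": LogNormalSpec(12.0, 0.35, 2.0, 60.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort (defaults emulate the study designs)."""

    n_subjects: int = 20
    distributions: dict = field(default_factory=_default_distributions)
    noise: NoiseModel = field(default_factory=NoiseModel)
    #: exponent of the compensatory fasting-hyperinsulinemia coupling:
    #: the basal-insulin median scales with (k5 / median k5)^(-coupling),
    #: so less insulin-sensitive subjects run higher fasting insulin
    insulin_resistance_coupling: float = 0.5
    plasma_missing_prob: float = 0.0   # per blood draw
    cgm_missing_prob: float = 0.0      # whole trace absent
    cgm_irregular_prob: float = 0.0    # trace rendered non-uniform
    ogtt_times: np.ndarray = field(
        default_factory=lambda: OGTT_DESIGN_TIMES.copy())
    cgm_times: np.ndarray = field(
        default_factory=lambda: CGM_DESIGN_TIMES.copy())
    glucose_dose: float = 75.0         # g
    max_redraws: int = 5

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in ("plasma_missing_prob", "cgm_missing_prob",
                  "cgm_irregular_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be a probability")

    def replace(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


@dataclass
class SyntheticSubject:
    """Ground truth and measured (noisy) view of one synthetic person."""

    subject_id: str
    true_parameters: EstimableParameters
    context: SubjectContext
    clean: Trajectory
    response: SubjectResponse


def sample_subject(spec: CohortSpec, rng: np.random.Generator,
                   fixed: FixedParameters,
                   subject_id: str = "s001") -> SyntheticSubject:
    """Draw one subject, simulate the OGTT and apply the noise model."""
    dists = spec.distributions
    for _ in range(spec.max_redraws):
        est = EstimableParameters(
            k1=dists["k1"].draw(rng), k5=dists["k5"].draw(rng),
            k6=dists["k6"].draw(rng), tau_g=dists["tau_g"].draw(rng))
        ins_dist = dists["basal_insulin"]
        if spec.insulin_resistance_coupling != 0.0:
            # compensatory fasting hyperinsulinemia: lower k5 -> higher Ib
            factor = ((est.k5 / dists["k5"].median)
                      ** (-spec.insulin_resistance_coupling))
            ins_dist = LogNormalSpec(ins_dist.median * factor,
                                     ins_dist.sigma_log,
                                     ins_dist.lower, ins_dist.upper)
        ctx = SubjectContext(
            body_mass=dists["body_mass"].draw(rng),
            glucose_dose=spec.glucose_dose,
            basal_plasma_glucose=dists["basal_glucose"].draw(rng),
            basal_insulin=ins_dist.draw(rng))
        grid = np.union1d(spec.ogtt_times, spec.cgm_times)
        try:
            clean = simulate(est, fixed, ctx, grid, keep_states=False)
        except SimulationError:
            continue
        break
    else:
        raise SimulationError(
            f"no simulable draw for {subject_id} after "
            f"{spec.max_redraws} attempts")

    gi = np.searchsorted(grid, spec.ogtt_times)
    ci = np.searchsorted(grid, spec.cgm_times)
    glu, ins = spec.noise.apply_plasma(clean.plasma_glucose[gi],
                                       clean.plasma_insulin[gi], rng)
    cgm = spec.noise.apply_cgm(clean.interstitial_glucose[ci], rng)
    response = SubjectResponse(
        subject_id=subject_id, visit="baseline",
        ogtt_times=spec.ogtt_times.copy(),
        plasma_glucose=glu, plasma_insulin=ins,
        cgm_times=spec.cgm_times.copy(), cgm_glucose=cgm,
        body_mass=ctx.body_mass, glucose_dose=spec.glucose_dose)
    return SyntheticSubject(subject_id=subject_id, true_parameters=est,
                            context=ctx, clean=clean, response=response)


def inject_missingness(subject: SyntheticSubject, spec: CohortSpec,
                       rng: np.random.Generator) -> SubjectResponse:
    """Remove samples / perturb the CGM grid per the configured
    probabilities, returning a new response (the subject is unchanged)."""
    r = subject.response
    glu = r.plasma_glucose.copy()
    ins = r.plasma_insulin.copy()
    drop = rng.random(glu.shape) < spec.plasma_missing_prob
    glu[drop] = np.nan
    ins[drop] = np.nan

    cgm_t, cgm_g = r.cgm_times, r.cgm_glucose
    if cgm_t is not None and rng.random() < spec.cgm_missing_prob:
        cgm_t = cgm_g = None
    elif cgm_t is not None and rng.random() < spec.cgm_irregular_prob:
        # drop one interior sensor reading: the remaining grid is no
        # longer uniformly 5 min, as in an irregular-frequency file
        j = int(rng.integers(1, cgm_t.size - 1))
        keep = np.ones(cgm_t.size, dtype=bool)
        keep[j] = False
        cgm_t, cgm_g = cgm_t[keep].copy(), cgm_g[keep].copy()

    return r.replace(plasma_glucose=glu, plasma_insulin=ins,
                     cgm_times=cgm_t, cgm_glucose=cgm_g)


#: exclusion reasons, phrased as data-cleaning rules
REASON_MISSING_BASELINE = "missing baseline (t = 0 min) sample"
REASON_MISSING_TWO_HOUR = "missing 2-hour post-load sample"
REASON_TOO_MANY_MISSING = "more than two missing samples"
REASON_IRREGULAR_CGM = "irregular CGM measurement frequency"
REASON_MISSING_CHANNEL = "missing set of glucose measurements"


def apply_exclusions(responses) -> tuple[list, list]:
    """Split responses into (kept, excluded-with-reasons).

    A response is excluded when it misses a whole glucose channel (OGTT or
    CGM), has more than two missing blood draws, misses the baseline or
    2-hour draw, or its CGM grid is not uniformly 5 min.
    """
    kept, excluded = [], []
    for r in responses:
        reasons = []
        if r.cgm_times is None or np.all(np.isnan(r.plasma_glucose)):
            reasons.append(REASON_MISSING_CHANNEL)
        else:
            if not r.has_baseline:
                reasons.append(REASON_MISSING_BASELINE)
            if not r.has_two_hour:
                reasons.append(REASON_MISSING_TWO_HOUR)
            if r.n_missing_plasma > 2:
                reasons.append(REASON_TOO_MANY_MISSING)
            if not r.cgm_uniform_5min:
                reasons.append(REASON_IRREGULAR_CGM)
        if reasons:
            excluded.append((r, reasons))
        else:
            kept.append(r)
    return kept, excluded


def generate_cohort(spec: CohortSpec, seed: int,
                    fixed: FixedParameters | None = None
                    ) -> list[SyntheticSubject]:
    """Generate ``spec.n_subjects`` subjects, reproducibly from the seed.

    Missingness (when configured) is injected into each subject's
    ``response`` in place of the complete one.
    """
    if fixed is None:
        fixed = FixedParameters()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(spec.n_subjects):
        subj = sample_subject(spec, rng, fixed, subject_id=f"s{i:03d}")
        if (spec.plasma_missing_prob > 0 or spec.cgm_missing_prob > 0
                or spec.cgm_irregular_prob > 0):
            subj.response = inject_missingness(subj, spec, rng)
        subjects.append(subj)
    return subjects


def cohort_truth(subjects) -> pd.DataFrame:
    """Ground-truth parameter table for recovery scoring."""
    rows = []
    for s in subjects:
        rec = {"subject_id": s.subject_id, "visit": s.response.visit}
        rec.update(s.true_parameters.to_dict())
        rows.append(rec)
    return pd.DataFrame(rows)
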