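"""Per-subject parameter estimation by TikTak multistart least squares.

The calibration objective is a max-normalized sum of squares over the fitted
metabolites (one glucose channel and plasma insulin),

    L(theta) = sum_i sum_j ((y_ij - yhat_ij(theta)) / max(y_i))^2,

where the per-metabolite normalization ``max(y_i)`` puts glucose (mmol/L)
and insulin (mU/L) residuals on comparable scales.  The t = 0 samples are
model inputs, never fitted points.  In plasma mode the decision vector is
(k1, k5, k6); in cgm mode the plasma-to-interstitium lag tau_g is estimated
as well.

The global stage evaluates the objective on a scrambled Sobol design over
the search box, keeps the best points, and polishes them sequentially with
a bounded Nelder-Mead simplex started from convex blends between each kept
point and the best optimum found so far, with blending weight increasing
toward 1 (the TikTak schedule).  All randomness is owned by the configured
seed, so repeated runs are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .data import SubjectResponse
from .model_core import SimulationError, simulate
from .params import EstimableParameters, FixedParameters, SubjectContext

__all__ = [
    "ObservationSet",
    "CalibrationConfig",
    "CalibrationResult",
    "build_observations",
    "objective",
    "tiktak_calibrate",
    "fit_metrics",
]

#: absolute tolerance deciding whether an estimate sits on a search bound
BOUNDARY_ATOL = 1e-9


class UnusableResponseError(ValueError):
    """The response lacks an observable required by the requested mode."""


@dataclass
class ObservationSet:
    """Fitted data points of one response in one calibration mode."""

    glucose_source: str                 # "plasma" | "cgm"
    glucose_times: np.ndarray
    glucose_values: np.ndarray
    insulin_times: np.ndarray
    insulin_values: np.ndarray

    def __post_init__(self):
        # an empty channel is tolerated here (a glucose-only objective is
        # legitimate in sensitivity analyses); build_observations() rejects
        # it for regular calibration
        for name in ("glucose", "insulin"):
            t = np.asarray(getattr(self, f"{name}_times"), dtype=float)
            y = np.asarray(getattr(self, f"{name}_values"), dtype=float)
            setattr(self, f"{name}_times", t)
            setattr(self, f"{name}_values", y)
            if np.any(t <= 0):
                raise ValueError("t = 0 samples are model inputs, not "
                                 "fitted points")
            if np.any(np.isnan(y)):
                raise ValueError("fitted points must not be NaN")

    @property
    def glucose_norm(self) -> float:
        return float(np.max(self.glucose_values)) \
            if self.glucose_values.size else 1.0

    @property
    def insulin_norm(self) -> float:
        return float(np.max(self.insulin_values)) \
            if self.insulin_values.size else 1.0

    @property
    def n_points(self) -> int:
        return int(self.glucose_times.size + self.insulin_times.size)

    def loss(self, glucose_pred, insulin_pred) -> float:
        """Max-normalized sum of squares over both metabolites,

            L = sum_i sum_j ((y_ij - yhat_ij) / max(y_i))^2,

        for predictions aligned with the fitted points."""
        total = 0.0
        for y, yhat, norm in (
                (self.glucose_values, glucose_pred, self.glucose_norm),
                (self.insulin_values, insulin_pred, self.insulin_norm)):
            if y.size:
                r = (y - np.asarray(yhat, dtype=float)) / norm
                total += float(r @ r)
        return total


def build_observations(response: SubjectResponse,
                       mode: str) -> ObservationSet:
    """Assemble the fitted points of a response for one calibration mode.

    Plasma mode fits the post-load OGTT glucose samples, cgm mode the 5-min
    interstitial trace over the test window; plasma insulin is fitted in
    both.  Basal (t = 0) values are routed to :class:`SubjectContext`
    instead and missing samples are dropped.
    """
    ins_mask = (response.ogtt_times > 0) & ~np.isnan(response.plasma_insulin)
    ins_t = response.ogtt_times[ins_mask]
    ins_y = response.plasma_insulin[ins_mask]

    if mode == "plasma":
        glu_mask = ((response.ogtt_times > 0)
                    & ~np.isnan(response.plasma_glucose))
        glu_t = response.ogtt_times[glu_mask]
        glu_y = response.plasma_glucose[glu_mask]
    elif mode == "cgm":
        if response.cgm_times is None:
            raise UnusableResponseError(
                f"{response.key}: no CGM trace in cgm mode")
        glu_mask = (response.cgm_times > 0) & ~np.isnan(response.cgm_glucose)
        glu_t = response.cgm_times[glu_mask]
        glu_y = response.cgm_glucose[glu_mask]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if glu_t.size == 0:
        raise UnusableResponseError(f"{response.key}: empty glucose "
                                    "observable")
    if ins_t.size == 0:
        raise UnusableResponseError(f"{response.key}: empty insulin "
                                    "observable")
    return ObservationSet(mode, glu_t, glu_y, ins_t, ins_y)


#: default per-parameter search ranges; the k6 upper bound of 10.0 is the
#: reference value for boundary-estimate diagnostics
DEFAULT_RANGES = {
    "k1": (1e-3, 0.1),
    "k5": (1e-4, 0.5),
    "k6": (0.01, 10.0),
    "tau_g": (1e-6, 30.0),
}


@dataclass
class CalibrationConfig:
    """Search box and multistart budget of the calibration."""

    mode: str = "plasma"
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    n_global: int = 128       # Sobol points in the global stage
    n_local: int = 16         # local polishes (kept best points)
    local_xtol: float = 1e-6  # simplex tolerance on the unit box
    local_maxfev: int = 140   # function-evaluation cap per polish
    final_maxfev: int = 400   # cap of the final tight polish
    seed: int = 0
    penalty: float = 1e6      # objective assigned to failed simulations
    # TikTak blending weight schedule w_i = clip((i/N*)^power, lo, hi)
    blend_power: float = 2.0
    blend_lo: float = 0.1
    blend_hi: float = 0.995

    def __post_init__(self):
        if self.mode not in ("plasma", "cgm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_global < 1 or self.n_local < 1:
            raise ValueError("multistart counts must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name}: {lo} >= {hi}")

    @property
    def param_names(self) -> tuple:
        if self.mode == "cgm":
            return ("k1", "k5", "k6", "tau_g")
        return ("k1", "k5", "k6")

    def bounds(self) -> np.ndarray:
        return np.array([self.ranges[p] for p in self.param_names])

    def replace(self, **kw) -> "CalibrationConfig":
        return replace(self, **kw)


class ObjectiveEvaluator:
    """Callable computing L(theta) for one response, with the simulation
    grid and index bookkeeping precomputed.

    ``theta`` may be a full parameter vector in the order of
    ``config.param_names``, or a partial vector when some parameters are
    held fixed (profile likelihood re-optimization).
    """

    def __init__(self, obs: ObservationSet, fixed: FixedParameters,
                 ctx: SubjectContext, config: CalibrationConfig):
        self.obs = obs
        self.fixed = fixed
        self.ctx = ctx
        self.config = config
        self.names = config.param_names
        grid = np.union1d(np.concatenate(([0.0], obs.glucose_times)),
                          obs.insulin_times)
        self.t_eval = grid
        self._glu_idx = np.searchsorted(grid, obs.glucose_times)
        self._ins_idx = np.searchsorted(grid, obs.insulin_times)
        self._glu_norm = obs.glucose_norm
        self._ins_norm = obs.insulin_norm
        self._glu_observable = ("interstitial_glucose"
                                if obs.glucose_source == "cgm"
                                else "plasma_glucose")
        self.n_eval = 0

    def estimables(self, theta) -> EstimableParameters:
        kw = dict(zip(self.names, np.asarray(theta, dtype=float)))
        kw.setdefault("tau_g", None)
        return EstimableParameters(**kw)

    def predict(self, est: EstimableParameters) -> tuple:
        """Model predictions at the fitted points (glucose, insulin);
        raises SimulationError on integration failure or a trajectory
        with negative masses/concentrations."""
        traj = simulate(est, self.fixed, self.ctx, self.t_eval,
                        keep_states=True)
        if not traj.nonnegative:
            raise SimulationError("negative trajectory", est=est)
        g_hat = traj.observable(self._glu_observable)[self._glu_idx]
        i_hat = traj.plasma_insulin[self._ins_idx]
        return g_hat, i_hat

    def __call__(self, theta) -> float:
        self.n_eval += 1
        try:
            est = self.estimables(theta)
            g_hat, i_hat = self.predict(est)
        except (SimulationError, ValueError):
            return self.config.penalty
        return self.obs.loss(g_hat, i_hat)


def objective(est: EstimableParameters, obs: ObservationSet,
              fixed: FixedParameters, ctx: SubjectContext,
              penalty: float = 1e6) -> float:
    """Max-normalized sum-of-squares objective for one parameter set."""
    config = CalibrationConfig(mode=obs.glucose_source, penalty=penalty)
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    theta = [getattr(est, p) for p in config.param_names]
    return ev(theta)


@dataclass
class CalibrationResult:
    """Point estimates and diagnostics of one calibration run."""

    estimates: EstimableParameters
    objective_value: float
    mode: str
    mse: dict                     # native-unit MSE per observable
    residual_table: pd.DataFrame  # observable, time_min, observed, predicted
    boundary_hit: dict            # parameter -> bool
    n_local_converged: int
    seed: int
    success: bool = True

    @property
    def any_boundary(self) -> bool:
        return any(self.boundary_hit.values())

    def to_record(self) -> dict:
        rec = {"mode": self.mode, "objective": self.objective_value,
               "seed": self.seed, "success": self.success,
               "n_local_converged": self.n_local_converged}
        rec.update({k: v for k, v in self.estimates.to_dict().items()})
        rec.update({f"mse_{k}": v for k, v in self.mse.items()})
        rec.update({f"boundary_{k}": v for k, v in self.boundary_hit.items()})
        return rec


def _local_polish(ev, x0_unit, lo, span, xtol, maxfev):
    """Bounded Nelder-Mead on the unit box; returns (x_unit, f, converged).

    Coordinates that converge close to a box face are snapped onto it when
    that does not worsen the objective, so bound-constrained optima are
    reported exactly on the bound (as boundary diagnostics expect) instead
    of a simplex-tolerance away from it."""
    fun = lambda u: ev(lo + span * np.clip(u, 0.0, 1.0))
    res = minimize(fun, np.clip(x0_unit, 0.0, 1.0), method="Nelder-Mead",
                   bounds=[(0.0, 1.0)] * len(x0_unit),
                   options={"xatol": xtol, "fatol": 1e-12,
                            "maxfev": maxfev})
    x, f = np.clip(res.x, 0.0, 1.0), float(res.fun)
    snap_tol = max(1e-3, 10.0 * xtol)
    for j in range(x.size):
        for face in (0.0, 1.0):
            if 0.0 < abs(x[j] - face) <= snap_tol:
                trial = x.copy()
                trial[j] = face
                f_trial = fun(trial)
                if f_trial <= f + 1e-12:
                    x, f = trial, f_trial
    return x, f, bool(res.success)


def tiktak_calibrate(obs: ObservationSet, config: CalibrationConfig,
                     fixed: FixedParameters,
                     ctx: SubjectContext) -> CalibrationResult:
    """Fit the estimable parameters of one response.

    Runs the Sobol global stage, the sequence of blended local polishes and
    one final tight polish from the incumbent, then assembles diagnostics.
    Never raises on optimization failure: if every start fails to simulate,
    the result carries the penalty objective with all bounds flagged.
    """
    bounds = config.bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    d = len(lo)
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)

    sob = qmc.Sobol(d, scramble=True, rng=np.random.default_rng(config.seed))
    n_sobol = max(config.n_global, config.n_local)
    pts_unit = sob.random_base2(int(np.ceil(np.log2(n_sobol))))[:n_sobol]
    vals = np.array([ev(lo + span * u) for u in pts_unit])

    order = np.argsort(vals, kind="stable")[:config.n_local]
    starts = pts_unit[order]
    start_vals = vals[order]

    best_u = starts[0].copy()
    best_f = float(start_vals[0])
    n_conv = 0
    n_star = config.n_local
    for i, u_i in enumerate(starts, start=1):
        w = float(np.clip((i / n_star) ** config.blend_power,
                          config.blend_lo, config.blend_hi))
        x0 = (1.0 - w) * u_i + w * best_u
        x, f, ok = _local_polish(ev, x0, lo, span,
                                 xtol=max(config.local_xtol, 1e-6),
                                 maxfev=config.local_maxfev)
        # a polish counts as converged when it lands on a simulable
        # optimum (the evaluation cap, not the penalty region, ended it)
        n_conv += int(f < config.penalty)
        if f < best_f:
            best_f, best_u = f, x

    # final tight polish of the incumbent
    x, f, ok = _local_polish(ev, best_u, lo, span,
                             xtol=config.local_xtol,
                             maxfev=config.final_maxfev)
    if f < best_f:
        best_f, best_u = f, x

    theta = lo + span * best_u
    all_failed = best_f >= config.penalty
    if all_failed:
        theta = hi.copy()  # flag: pinned to the bounds, penalty objective
    est = ev.estimables(theta)
    boundary = {name: bool(min(abs(theta[j] - lo[j]),
                               abs(theta[j] - hi[j])) <= BOUNDARY_ATOL)
                for j, name in enumerate(config.param_names)}

    result = CalibrationResult(
        estimates=est,
        objective_value=float(ev(theta)),
        mode=config.mode,
        mse={}, residual_table=pd.DataFrame(),
        boundary_hit=boundary,
        n_local_converged=n_conv,
        seed=config.seed,
        success=not all_failed,
    )
    if not all_failed:
        mse, table = fit_metrics(result, obs, fixed, ctx)
        result.mse = mse
        result.residual_table = table
    return result


def fit_metrics(result: CalibrationResult, obs: ObservationSet,
                fixed: FixedParameters, ctx: SubjectContext):
    """Per-observable MSE in native units and residuals by time point."""
    config = CalibrationConfig(mode=obs.glucose_source)
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    g_hat, i_hat = ev.predict(result.estimates)
    res_glu = obs.glucose_values - g_hat   # native units, y - yhat
    res_ins = obs.insulin_values - i_hat
    mse = {"glucose": (float(np.mean(res_glu ** 2))
                       if res_glu.size else float("nan")),
           "insulin": (float(np.mean(res_ins ** 2))
                       if res_ins.size else float("nan"))}
    table = pd.DataFrame({
        "observable": (["glucose"] * len(res_glu)
                       + ["insulin"] * len(res_ins)),
        "time_min": np.concatenate([obs.glucose_times, obs.insulin_times]),
        "observed": np.concatenate([obs.glucose_values, obs.insulin_values]),
        "residual": np.concatenate([res_glu, res_ins]),
    })
    table["predicted"] = table["observed"] - table["residual"]
    return mse, table
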