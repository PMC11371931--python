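"""Profile-likelihood identifiability analysis and observable bands.

For each profiled parameter the objective is re-minimized over the remaining
free parameters at a sequence of fixed values walked outward from the
optimum.  The 95% confidence interval endpoint on each side is where the
profile crosses ``L* + Delta(alpha)`` with ``Delta`` the chi-square quantile
with one degree of freedom (the max-normalized least-squares objective is
treated as -2 log-likelihood up to a constant); the endpoint is refined by
bisection and reported as unbounded when no crossing occurs inside the scan
range.  A model/data combination is practically identifiable when every
profiled parameter has a finite interval strictly inside its scan range.
The lag tau_g, when present, is re-optimized as a nuisance parameter but is
never profiled itself.

Observable confidence bands are prediction profiles: at each of a coarse
set of times the model prediction is maximized/minimized over all parameter
sets whose objective stays below the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2, f as f_dist

from .calibration import (CalibrationConfig, CalibrationResult,
                          ObjectiveEvaluator, ObservationSet)
from .model_core import simulate
from .params import FixedParameters, SubjectContext

__all__ = [
    "ProfileCurve",
    "IdentifiabilityReport",
    "ConfidenceBand",
    "profile_parameter",
    "classify_identifiability",
    "observable_band",
]

#: parameters subjected to profile-likelihood analysis (tau_g excluded)
PROFILED_PARAMETERS = ("k1", "k5", "k6")


class NotProfilableError(RuntimeError):
    """The fit carries a penalty objective and cannot be profiled."""


def threshold_delta(alpha: float, objective_opt: float, n_points: int,
                    n_free: int, convention: str = "f_scaled",
                    df: int = 1) -> float:
    """Objective increase over the optimum defining the confidence region.

    The max-normalized least-squares objective is only a -2 log-likelihood
    up to an unknown noise-variance scale, so the default convention
    (``"f_scaled"``) uses the exact linear-Gaussian result for profile
    confidence regions with estimated variance,

        Delta = L* * df * F(alpha; df, n - p) / (n - p),

    where ``L*`` estimates (n - p) times the normalized noise variance.
    ``"chi2_scaled"`` replaces F by chi-square on the same variance
    estimate; ``"chi2_fixed"`` applies the raw chi-square quantile to the
    objective as-is (appropriate only when residuals are truly
    unit-variance normalized).
    """
    if convention == "chi2_fixed":
        return float(chi2.ppf(alpha, df))
    dof = max(n_points - n_free, 1)
    s2 = max(objective_opt, 1e-300) / dof
    if convention == "chi2_scaled":
        return float(chi2.ppf(alpha, df)) * s2
    if convention == "f_scaled":
        return df * float(f_dist.ppf(alpha, df, dof)) * s2
    raise ValueError(f"unknown threshold convention {convention!r}")


@dataclass
class ProfileCurve:
    """One parameter's profile: re-optimized objective vs fixed value."""

    parameter: str
    scan_values: np.ndarray
    scan_objectives: np.ndarray
    optimum_value: float
    optimum_objective: float
    scan_range: tuple
    threshold: float
    ci_lower: float | None          # None = no crossing inside scan range
    ci_upper: float | None

    @property
    def lower_bounded(self) -> bool:
        return self.ci_lower is not None

    @property
    def upper_bounded(self) -> bool:
        return self.ci_upper is not None

    def to_record(self) -> dict:
        return {
            "parameter": self.parameter,
            "optimum_value": self.optimum_value,
            "optimum_objective": self.optimum_objective,
            "scan_range": list(self.scan_range),
            "threshold": self.threshold,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "scan_values": self.scan_values.tolist(),
            "scan_objectives": self.scan_objectives.tolist(),
        }


@dataclass
class IdentifiabilityReport:
    """Finite/infinite CI classification across the profiled parameters."""

    intervals: dict                    # name -> (lower, upper), None = open
    identifiable: dict                 # name -> bool
    model_identifiable: bool
    unidentifiable_parameters: list = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "intervals": {k: [v[0], v[1]] for k, v in self.intervals.items()},
            "identifiable": dict(self.identifiable),
            "model_identifiable": self.model_identifiable,
            "unidentifiable_parameters": list(self.unidentifiable_parameters),
        }


@dataclass
class ConfidenceBand:
    observable: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float


def profile_objective_1d(fun, theta_hat: float, objective_hat: float,
                         threshold: float, scan_range: tuple,
                         xtol: float = 1e-4, n_walk: int = 8):
    """Scan a scalar objective outward from its optimum on both sides.

    ``fun`` maps a parameter value to the (re-optimized) objective.  Returns
    ``(values, objectives, ci_lower, ci_upper)`` where an endpoint is None
    when the objective never exceeds ``threshold`` before the scan bound.
    The crossing is refined by bisection to absolute tolerance ``xtol``.
    """
    lo, hi = scan_range
    values = [theta_hat]
    objectives = [objective_hat]
    endpoints = {}
    for side, bound in (("lower", lo), ("upper", hi)):
        if hasattr(fun, "reset"):
            fun.reset()  # start each side's walk from the optimum
        gap = bound - theta_hat
        if gap == 0.0:
            endpoints[side] = None
            continue
        fracs = np.array([0.05, 0.12, 0.25, 0.42, 0.62, 0.8, 0.92, 1.0])
        prev_v, prev_f = theta_hat, objective_hat
        crossing = None
        for fr in fracs[:n_walk]:
            v = theta_hat + fr * gap
            f = fun(v)
            values.append(v)
            objectives.append(f)
            if f > threshold:
                crossing = (prev_v, v)
                break
            prev_v, prev_f = v, f
        if crossing is None:
            endpoints[side] = None
            continue
        a, b = crossing  # f(a) <= threshold < f(b)
        while abs(b - a) > xtol:
            m = 0.5 * (a + b)
            fm = fun(m)
            values.append(m)
            objectives.append(fm)
            if fm > threshold:
                b = m
            else:
                a = m
        endpoints[side] = 0.5 * (a + b)
    order = np.argsort(values)
    return (np.asarray(values)[order], np.asarray(objectives)[order],
            endpoints["lower"], endpoints["upper"])


class _ReoptimizedProfile:
    """Profile function: objective re-minimized over the free parameters
    (warm-started from the previous scan point)."""

    def __init__(self, ev: ObjectiveEvaluator, which: str,
                 theta_full: np.ndarray, bounds: np.ndarray,
                 maxfev: int | None = None, xtol: float = 5e-3):
        self.ev = ev
        names = list(ev.names)
        self.j = names.index(which)
        self.free = [i for i in range(len(names)) if i != self.j]
        self.lo = bounds[:, 0]
        self.span = bounds[:, 1] - bounds[:, 0]
        self.theta = theta_full.copy()
        self._u_hat = ((theta_full[self.free] - self.lo[self.free])
                       / self.span[self.free])
        self._warm = self._u_hat.copy()
        self.maxfev = 50 * len(self.free) if maxfev is None else maxfev
        self.xtol = xtol

    def reset(self):
        self._warm = self._u_hat.copy()

    def _full(self, value, u_free):
        theta = self.theta.copy()
        theta[self.j] = value
        theta[self.free] = (self.lo[self.free]
                            + self.span[self.free] * np.clip(u_free, 0, 1))
        return theta

    def _minimize(self, fun, start):
        return minimize(fun, np.clip(start, 0, 1), method="Nelder-Mead",
                        bounds=[(0.0, 1.0)] * len(self.free),
                        options={"xatol": self.xtol, "fatol": 1e-12,
                                 "maxfev": self.maxfev})

    def __call__(self, value: float) -> float:
        fun = lambda u: self.ev(self._full(value, u))
        res = self._minimize(fun, self._warm)
        penalty = self.ev.config.penalty
        if res.fun >= penalty and not np.allclose(self._warm, self._u_hat):
            # the warm start was stranded on the penalty plateau; retry
            # from the fitted optimum before accepting the penalty value
            res2 = self._minimize(fun, self._u_hat)
            if res2.fun < res.fun:
                res = res2
        if res.fun < penalty:
            self._warm = np.clip(res.x, 0, 1)
        return float(res.fun)


def profile_parameter(fit: CalibrationResult, obs: ObservationSet,
                      fixed: FixedParameters, ctx: SubjectContext,
                      which: str, config: CalibrationConfig | None = None,
                      scan_range: tuple | None = None,
                      alpha: float = 0.95,
                      convention: str = "f_scaled",
                      endpoint_xtol: float = 1e-4) -> ProfileCurve:
    """Profile one of k1, k5, k6 around a converged calibration."""
    if which not in PROFILED_PARAMETERS:
        raise ValueError(f"{which!r} is not subject to profiling "
                         f"(choose from {PROFILED_PARAMETERS})")
    if config is None:
        config = CalibrationConfig(mode=fit.mode)
    if not fit.success or fit.objective_value >= config.penalty:
        raise NotProfilableError("fit carries a penalty objective")

    bounds = config.bounds()
    if scan_range is None:
        scan_range = tuple(config.ranges[which])
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    theta_full = np.array([getattr(fit.estimates, p)
                           for p in config.param_names], dtype=float)
    prof = _ReoptimizedProfile(ev, which, theta_full, bounds)
    thr = fit.objective_value + threshold_delta(
        alpha, fit.objective_value, obs.n_points, len(config.param_names),
        convention=convention)
    theta_hat = float(theta_full[prof.j])

    values, objectives, ci_lo, ci_hi = profile_objective_1d(
        prof, theta_hat, fit.objective_value, thr, scan_range,
        xtol=endpoint_xtol)
    # re-optimization can only equal or exceed the global optimum; clamp
    # the tiny negative slack a loose inner optimizer may produce
    objectives = np.maximum(objectives, fit.objective_value)
    return ProfileCurve(
        parameter=which, scan_values=values, scan_objectives=objectives,
        optimum_value=theta_hat, optimum_objective=fit.objective_value,
        scan_range=scan_range, threshold=thr,
        ci_lower=ci_lo, ci_upper=ci_hi)


def classify_identifiability(curves) -> IdentifiabilityReport:
    """Classify parameters (and the model) from their profile curves.

    A parameter is practically identifiable when both CI endpoints exist
    and lie strictly inside the scan range; an endpoint exactly on the scan
    bound is conservatively treated as unbounded.
    """
    intervals, flags = {}, {}
    for c in curves:
        lo, hi = c.scan_range
        cl = c.ci_lower if (c.ci_lower is not None and c.ci_lower > lo) else None
        cu = c.ci_upper if (c.ci_upper is not None and c.ci_upper < hi) else None
        intervals[c.parameter] = (cl, cu)
        flags[c.parameter] = cl is not None and cu is not None
    bad = [p for p, ok in flags.items() if not ok]
    return IdentifiabilityReport(
        intervals=intervals, identifiable=flags,
        model_identifiable=not bad, unidentifiable_parameters=bad)


def identifiability_report(fit, obs, fixed, ctx,
                           config=None, alpha: float = 0.95,
                           convention: str = "f_scaled"):
    """Profile all of k1, k5, k6 and classify the model."""
    curves = [profile_parameter(fit, obs, fixed, ctx, p, config=config,
                                alpha=alpha, convention=convention)
              for p in PROFILED_PARAMETERS]
    report = classify_identifiability(curves)
    return report, curves


def observable_band(fit: CalibrationResult, obs: ObservationSet,
                    fixed: FixedParameters, ctx: SubjectContext,
                    observable: str, times: np.ndarray,
                    alpha: float = 0.95,
                    convention: str = "f_scaled",
                    config: CalibrationConfig | None = None,
                    n_anchor: int = 9) -> ConfidenceBand:
    """Prediction-profile confidence band of glucose or insulin.

    At ``n_anchor`` coarse times the prediction is pushed up/down over the
    parameter sets whose objective stays within ``Delta(alpha)`` of the
    optimum (inequality-constrained COBYLA search on the unit box), then
    the band is interpolated to ``times``.  The point simulation is always
    contained in the band.
    """
    if config is None:
        config = CalibrationConfig(mode=fit.mode)
    times = np.asarray(times, dtype=float)
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    bounds = config.bounds()
    lo, span = bounds[:, 0], bounds[:, 1] - bounds[:, 0]
    thr = fit.objective_value + threshold_delta(
        alpha, fit.objective_value, obs.n_points, len(config.param_names),
        convention=convention)
    obs_name = {"glucose": ev._glu_observable, "insulin": "plasma_insulin"}[
        observable]

    t_eval = np.union1d([0.0], times)
    idx = np.searchsorted(t_eval, times)

    def predict(u):
        est = ev.estimables(lo + span * np.clip(u, 0, 1))
        try:
            traj = simulate(est, fixed, ctx, t_eval, keep_states=False)
        except Exception:
            return None
        return traj.observable(obs_name)[idx]

    theta_hat = np.array([getattr(fit.estimates, p)
                          for p in config.param_names])
    u_hat = (theta_hat - lo) / span
    point = predict(u_hat)

    anchors = np.unique(np.round(
        np.linspace(times[0], times[-1], min(n_anchor, times.size))))
    anchor_idx = [int(np.argmin(np.abs(times - a))) for a in anchors]
    band_lo_a, band_hi_a = [], []
    constraint = {"type": "ineq", "fun": lambda u: thr - ev(lo + span * np.clip(u, 0, 1))}
    for ai in anchor_idx:
        extremes = []
        for sign in (+1.0, -1.0):
            def fobj(u, ai=ai, sign=sign):
                y = predict(u)
                if y is None:
                    return config.penalty
                return sign * y[ai]
            res = minimize(fobj, u_hat, method="COBYLA",
                           constraints=[constraint],
                           options={"rhobeg": 0.08, "maxiter": 60,
                                    "tol": 1e-4})
            u_fin = np.clip(res.x, 0, 1)
            y = predict(u_fin)
            ok = y is not None and ev(lo + span * u_fin) <= thr + 1e-6
            extremes.append(y[ai] if ok else point[ai])
        band_lo_a.append(min(extremes + [point[ai]]))
        band_hi_a.append(max(extremes + [point[ai]]))

    t_a = times[anchor_idx]
    lower = np.interp(times, t_a, band_lo_a)
    upper = np.interp(times, t_a, band_hi_a)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return ConfidenceBand(observable=observable, times=times,
                          lower=lower, upper=upper, alpha=alpha)
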