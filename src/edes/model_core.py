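"""E-DES ODE core: gut, plasma glucose, plasma insulin, remote insulin
action, and an interstitial glucose compartment.

The model tracks six states::

    M_gut   glucose mass in the gut                       (mg)
    G_pl    plasma glucose concentration                  (mmol/L)
    I_pl    plasma insulin concentration                  (mU/L)
    I_rem   remote insulin action above basal             (mU/L)
    D_int   accumulated glucose elevation, integral term  (mmol*min/L)
    G_int   interstitial glucose concentration            (mmol/L)

Plasma glucose balances endogenous production (suppressed by glucose
elevation and by remote insulin), gut appearance, insulin-independent
Michaelis-Menten uptake, insulin-dependent uptake (gain ``k5`` on remote
insulin action) and renal excretion above a threshold.  Insulin secretion is
a PID-style response to the glucose elevation above basal: a proportional
gain ``k6``, an integral term on the accumulated elevation and a derivative
term on dG_pl/dt (the model's own analytic derivative, keeping the
right-hand side smooth).  The interstitial compartment is a pure first-order
lag, dG_int/dt = (G_pl - G_int)/tau_g, so CGM glucose can be simulated and
fitted; tau_g = 0 (or None) is handled as the algebraic limit
G_int == G_pl.

The basal state is an exact equilibrium of the system by construction: the
insulin-independent uptake scale is closed so that all fluxes balance at the
subject's basal glucose and insulin, and remote insulin action is expressed
as a deviation from basal (zero at rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .params import EstimableParameters, FixedParameters, SubjectContext

__all__ = [
    "StateVector",
    "Trajectory",
    "SimulationError",
    "basal_initial_state",
    "meal_input_rate",
    "derivatives",
    "simulate",
]

# state indices
I_MGUT, I_GPL, I_IPL, I_IREM, I_DINT, I_GINT = range(6)

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8

#: trajectories dipping below this are treated as structurally negative
NONNEG_TOL = -1e-6


class SimulationError(RuntimeError):
    """Integration failed; carries the parameters so calibration can
    convert the failure into a penalty objective."""

    def __init__(self, message, est=None):
        super().__init__(message)
        self.est = est


@dataclass(frozen=True)
class StateVector:
    gut_glucose_mass: float       # mg
    plasma_glucose: float         # mmol/L
    plasma_insulin: float         # mU/L
    remote_insulin: float         # mU/L above basal
    integrator_state: float       # mmol*min/L
    interstitial_glucose: float   # mmol/L

    def as_array(self) -> np.ndarray:
        return np.array([
            self.gut_glucose_mass, self.plasma_glucose, self.plasma_insulin,
            self.remote_insulin, self.integrator_state,
            self.interstitial_glucose,
        ])


@dataclass
class Trajectory:
    """Simulated time courses of the model observables."""

    times: np.ndarray
    plasma_glucose: np.ndarray
    plasma_insulin: np.ndarray
    interstitial_glucose: np.ndarray
    states: np.ndarray | None = field(default=None, repr=False)

    def observable(self, name: str) -> np.ndarray:
        return {"glucose": self.plasma_glucose,
                "plasma_glucose": self.plasma_glucose,
                "insulin": self.plasma_insulin,
                "plasma_insulin": self.plasma_insulin,
                "cgm": self.interstitial_glucose,
                "interstitial_glucose": self.interstitial_glucose}[name]

    @property
    def nonnegative(self) -> bool:
        """True when masses and concentrations stay non-negative (the
        remote-insulin deviation state is exempt)."""
        lo = NONNEG_TOL
        arrs = [self.plasma_glucose, self.plasma_insulin,
                self.interstitial_glucose]
        if self.states is not None:
            arrs.append(self.states[:, I_MGUT])
        return all(float(np.min(a)) >= lo for a in arrs)


def basal_initial_state(ctx: SubjectContext,
                        est: EstimableParameters,
                        fixed: FixedParameters) -> StateVector:
    """Equilibrium state of the model with no meal input.

    Gut mass and the secretion integral start at zero, plasma glucose and
    insulin at their measured basal values, remote insulin action at its
    basal balance (zero, being a deviation state), and interstitial glucose
    at the basal interstitial value (plasma basal when absent).  The
    insulin-independent uptake scale that closes the basal flux balance is a
    function of the context alone and is applied consistently inside
    :func:`derivatives`.
    """
    # context validity is enforced by SubjectContext itself; re-check the
    # pieces the equilibrium depends on for defensive clarity
    if ctx.basal_plasma_glucose <= 0 or ctx.basal_insulin <= 0:
        raise ValueError("invalid context: basal values must be positive")
    return StateVector(
        gut_glucose_mass=0.0,
        plasma_glucose=ctx.basal_plasma_glucose,
        plasma_insulin=ctx.basal_insulin,
        remote_insulin=0.0,
        integrator_state=0.0,
        interstitial_glucose=ctx.interstitial_basal,
    )


def _uptake_scale(ctx: SubjectContext, fixed: FixedParameters) -> float:
    """Insulin-independent uptake scale closing the basal flux balance.

    At basal (no meal, zero remote insulin action, glucose below the renal
    threshold) endogenous production equals insulin-independent uptake,
    which fixes the scale ``c1`` of the Michaelis-Menten uptake term."""
    gb = ctx.basal_plasma_glucose
    return fixed.egp_basal * (fixed.km + gb) / gb


def meal_input_rate(t: float,
                    ctx: SubjectContext,
                    est: EstimableParameters,
                    fixed: FixedParameters) -> float:
    """Rate of glucose appearance into the gut (mg/min) at time ``t``.

    The drink empties into the gut with a Weibull-shaped rate whose time
    scale is the estimable ``k1``; the rate integrates to the bioavailable
    dose over [0, inf), so glucose mass is conserved through the gut.
    """
    if t < 0:
        raise ValueError("meal time must be >= 0")
    dose_mg = ctx.glucose_dose * 1000.0 * fixed.f_bio
    if dose_mg == 0.0 or t == 0.0:
        return 0.0
    k1, s = est.k1, fixed.sigma
    x = k1 * t
    return dose_mg * s * k1 * x ** (s - 1.0) * np.exp(-(x ** s))


def derivatives(t: float,
                state: np.ndarray,
                est: EstimableParameters,
                fixed: FixedParameters,
                ctx: SubjectContext) -> np.ndarray:
    """Right-hand side of the ODE system (time units: minutes)."""
    m_gut, g_pl, i_pl, i_rem, _d_int, g_int = state

    gb = ctx.basal_plasma_glucose
    ib = ctx.basal_insulin
    vol = fixed.v_g * ctx.body_mass  # glucose distribution volume, L

    # --- gut ---
    d_mgut = meal_input_rate(t, ctx, est, fixed) - fixed.k2 * m_gut
    g_gut = fixed.k2 * m_gut * fixed.f_conv / vol  # mmol/L/min into plasma

    # --- plasma glucose ---
    mm = g_pl / (fixed.km + g_pl)
    g_liv = (fixed.egp_basal - fixed.k3 * (g_pl - gb)
             - fixed.k4 * fixed.beta * i_rem)
    g_nonit = _uptake_scale(ctx, fixed) * mm
    g_it = est.k5 * fixed.beta * i_rem * mm
    g_ren = 0.0
    if g_pl > fixed.g_renal_threshold:
        g_ren = (fixed.renal_clearance / vol) * (g_pl - fixed.g_renal_threshold)
    d_gpl = g_liv + g_gut - g_nonit - g_it - g_ren

    # --- insulin secretion (PID on glucose elevation) and kinetics ---
    i_pnc = (est.k6 * (g_pl - gb)
             + (fixed.k7 / fixed.tau_i) * _d_int
             + fixed.k8 * fixed.tau_d * d_gpl) / fixed.beta
    d_ipl = i_pnc - fixed.insulin_clearance * (i_pl - ib)
    d_irem = fixed.k9 * (i_pl - ib) - fixed.k10 * i_rem
    d_dint = g_pl - gb

    # --- interstitial glucose: first-order lag toward plasma ---
    tau = est.tau_g
    if tau is None or tau == 0.0:
        d_gint = 0.0  # handled algebraically as G_int == G_pl by simulate()
    else:
        d_gint = (g_pl - g_int) / tau

    return np.array([d_mgut, d_gpl, d_ipl, d_irem, d_dint, d_gint])


def simulate(est: EstimableParameters,
             fixed: FixedParameters,
             ctx: SubjectContext,
             t_eval: np.ndarray,
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL,
             keep_states: bool = True) -> Trajectory:
    """Integrate the model from the basal equilibrium over ``t_eval``.

    ``t_eval`` must be strictly increasing and start at 0.  The integrator
    is the adaptive stiff-switching LSODA method; the run is deterministic
    for identical inputs and tolerances.  Failures raise
    :class:`SimulationError` carrying the parameter values so calibration
    can assign a penalty objective.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval.size < 1:
        raise ValueError("t_eval must be a 1-d grid")
    if t_eval[0] != 0.0 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing and start at 0")

    y0 = basal_initial_state(ctx, est, fixed).as_array()
    identity_interstitial = est.tau_g is None or est.tau_g == 0.0

    # Localize everything the rhs needs; odeint's f(y, t) convention.
    k2, sigma, f_bio = fixed.k2, fixed.sigma, fixed.f_bio
    egp, k3, k4 = fixed.egp_basal, fixed.k3, fixed.k4
    km, gth, cren = fixed.km, fixed.g_renal_threshold, fixed.renal_clearance
    k7_ti, k8_td = fixed.k7 / fixed.tau_i, fixed.k8 * fixed.tau_d
    k9, k10, iclr = fixed.k9, fixed.k10, fixed.insulin_clearance
    beta, fconv = fixed.beta, fixed.f_conv
    k1, k5, k6 = est.k1, est.k5, est.k6
    tau = 0.0 if identity_interstitial else est.tau_g
    gb, ib = ctx.basal_plasma_glucose, ctx.basal_insulin
    vol = fixed.v_g * ctx.body_mass
    dose_mg = ctx.glucose_dose * 1000.0 * f_bio
    c1 = egp * (km + gb) / gb
    exp = np.exp

    def rhs(y, t):
        m_gut, g_pl, i_pl, i_rem, d_int, g_int = y
        if dose_mg != 0.0 and t > 0.0:
            x = k1 * t
            meal = dose_mg * sigma * k1 * x ** (sigma - 1.0) * exp(-(x ** sigma))
        else:
            meal = 0.0
        d_mgut = meal - k2 * m_gut
        mm = g_pl / (km + g_pl)
        d_gpl = (egp - k3 * (g_pl - gb) - k4 * beta * i_rem
                 + k2 * m_gut * fconv / vol
                 - c1 * mm - k5 * beta * i_rem * mm)
        if g_pl > gth:
            d_gpl -= (cren / vol) * (g_pl - gth)
        i_pnc = (k6 * (g_pl - gb) + k7_ti * d_int + k8_td * d_gpl) / beta
        d_ipl = i_pnc - iclr * (i_pl - ib)
        d_irem = k9 * (i_pl - ib) - k10 * i_rem
        d_gint = 0.0 if tau == 0.0 else (g_pl - g_int) / tau
        return (d_mgut, d_gpl, d_ipl, d_irem, g_pl - gb, d_gint)

    # odeint needs at least two time points; pad a pure-t=0 request
    t_ode = t_eval if t_eval.size > 1 else np.array([0.0, 1.0])
    with np.errstate(over="ignore", invalid="ignore"):
        ys, info = odeint(rhs, y0, t_ode, rtol=rtol, atol=atol,
                          full_output=True, mxstep=5000)
    if info["message"] != "Integration successful." or not np.all(np.isfinite(ys)):
        raise SimulationError(
            f"integration failed: {info['message']}", est=est)
    ys = ys[: t_eval.size]

    if identity_interstitial:
        ys[:, I_GINT] = ys[:, I_GPL]

    return Trajectory(
        times=t_eval,
        plasma_glucose=ys[:, I_GPL].copy(),
        plasma_insulin=ys[:, I_IPL].copy(),
        interstitial_glucose=ys[:, I_GINT].copy(),
        states=ys if keep_states else None,
    )
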