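"""Unit and property tests of the ODE core: equilibrium, mass
conservation, the interstitial lag, and solver behavior."""

import numpy as np
import pytest
from scipy.integrate import odeint

from edes import (EstimableParameters, FixedParameters, SubjectContext,
                  basal_initial_state, derivatives, meal_input_rate,
                  simulate)
from edes.model_core import I_GINT


def test_basal_state_is_equilibrium(fixed, ctx, truth):
    """With no meal the basal state is an exact fixed point: the RHS
    vanishes and a 300-min simulation stays at basal."""
    ctx0 = ctx.replace(glucose_dose=0.0)
    state = basal_initial_state(ctx0, truth, fixed)
    rhs = derivatives(0.0, state.as_array(), truth, fixed, ctx0)
    assert np.max(np.abs(rhs)) < 1e-10

    tr = simulate(truth, fixed, ctx0, np.arange(0.0, 301.0, 5.0))
    assert np.max(np.abs(tr.plasma_glucose - ctx0.basal_plasma_glucose)) < 1e-6
    assert np.max(np.abs(tr.plasma_insulin - ctx0.basal_insulin)) < 1e-6
    assert np.max(np.abs(tr.interstitial_glucose
                         - ctx0.interstitial_basal)) < 1e-6


def test_basal_interstitial_falls_back_to_plasma(fixed, truth):
    ctx = SubjectContext(80.0, 0.0, 5.0, 10.0)
    state = basal_initial_state(ctx, truth, fixed)
    assert state.interstitial_glucose == 5.0


def test_invalid_context_rejected():
    with pytest.raises(ValueError):
        SubjectContext(80.0, 75.0, -5.0, 10.0)
    with pytest.raises(ValueError):
        SubjectContext(80.0, 75.0, 5.0, 0.0)
    with pytest.raises(ValueError):
        SubjectContext(0.0, 75.0, 5.0, 10.0)


def test_interstitial_lag_arithmetic(fixed, ctx):
    """dG_i/dt = (G_pl - G_i)/tau_g: 7 vs 5 mmol/L at tau 2 gives 1."""
    est = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=2.0)
    state = basal_initial_state(ctx, est, fixed).as_array()
    state[1] = 7.0   # plasma glucose
    state[5] = 5.0   # interstitial glucose
    d = derivatives(0.0, state, est, fixed, ctx)
    assert d[I_GINT] == pytest.approx(1.0, abs=1e-12)


def test_renal_flux_zero_below_threshold(fixed, ctx, truth):
    """Below the renal threshold the glucose balance has no excretion:
    raising the threshold further must not change dG_pl/dt."""
    state = basal_initial_state(ctx, truth, fixed).as_array()
    state[1] = fixed.g_renal_threshold - 0.5
    d_lo = derivatives(0.0, state, truth, fixed, ctx)
    d_hi = derivatives(0.0, state, truth, fixed,
                       ctx)  # same state, threshold inactive
    higher = fixed.replace(g_renal_threshold=fixed.g_renal_threshold + 5.0)
    d_alt = derivatives(0.0, state, truth, higher, ctx)
    assert d_lo[1] == pytest.approx(d_alt[1], abs=1e-12)
    assert d_lo[1] == pytest.approx(d_hi[1], abs=1e-12)


def test_meal_input_zero_dose_and_domain(fixed, ctx, truth):
    ctx0 = ctx.replace(glucose_dose=0.0)
    assert all(meal_input_rate(t, ctx0, truth, fixed) == 0.0
               for t in (0.0, 5.0, 60.0))
    with pytest.raises(ValueError):
        meal_input_rate(-1.0, ctx, truth, fixed)


def test_meal_input_mass_conserved(fixed, ctx, truth):
    """The gut-appearance rate integrates to the bioavailable dose."""
    t = np.linspace(0.0, 2000.0, 20001)
    rate = np.array([meal_input_rate(ti, ctx, truth, fixed) for ti in t])
    assert rate.min() >= 0.0
    total_mg = np.trapezoid(rate, t)
    expected = ctx.glucose_dose * 1000.0 * fixed.f_bio
    assert total_mg == pytest.approx(expected, rel=1e-4)


def test_doubling_k1_advances_appearance_peak(fixed, ctx, truth):
    t = np.linspace(0.0, 300.0, 3001)
    fast = truth.replace(k1=2 * truth.k1)
    peak = lambda est: t[np.argmax([meal_input_rate(ti, ctx, est, fixed)
                                    for ti in t])]
    assert peak(fast) < peak(truth)


def test_ramp_lag_matches_closed_form(fixed, ctx):
    """For a prescribed plasma ramp G_pl = Gb + m t the interstitial
    equation has the closed form G_i = Gb + m(t - tau(1 - exp(-t/tau)))."""
    m, tau = 0.05, 4.0
    gb = ctx.basal_plasma_glucose
    est = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=tau)
    base = basal_initial_state(ctx, est, fixed).as_array()

    def rhs(gi, t):
        state = base.copy()
        state[1] = gb + m * t
        state[I_GINT] = float(gi[0])
        return derivatives(t, state, est, fixed, ctx)[I_GINT]

    t = np.linspace(0.0, 120.0, 241)
    num = odeint(rhs, gb, t, rtol=1e-10, atol=1e-12).ravel()
    exact = gb + m * (t - tau * (1.0 - np.exp(-t / tau)))
    assert np.max(np.abs(num - exact)) < 1e-6


def test_tau_zero_is_algebraic_identity(fixed, ctx):
    est = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=0.0)
    tr = simulate(est, fixed, ctx, np.arange(0.0, 131.0, 5.0))
    assert np.array_equal(tr.interstitial_glucose, tr.plasma_glucose)


def test_lag_vanishes_as_tau_shrinks(fixed, ctx):
    """sup|G_i - G_pl| decreases monotonically as tau_g -> 0 and is
    negligible at tau_g = 1e-6 min."""
    t = np.arange(0.0, 131.0, 5.0)
    sups = []
    for tau in (1.0, 1e-3, 1e-6):
        est = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=tau)
        tr = simulate(est, fixed, ctx, t)
        sups.append(np.max(np.abs(tr.interstitial_glucose
                                  - tr.plasma_glucose)))
    assert sups[0] > sups[1] > sups[2]
    assert sups[2] < 1e-4


def test_interstitial_peak_lags_plasma_peak(fixed, ctx):
    t = np.arange(0.0, 241.0, 1.0)
    for tau, strict in ((1.0, True), (5.0, True)):
        est = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=tau)
        tr = simulate(est, fixed, ctx, t)
        tp = t[np.argmax(tr.plasma_glucose)]
        ti = t[np.argmax(tr.interstitial_glucose)]
        assert ti > tp if strict else ti >= tp


def test_solver_refinement_stable(fixed, ctx, truth):
    t = np.arange(0.0, 131.0, 5.0)
    a = simulate(truth, fixed, ctx, t)
    b = simulate(truth, fixed, ctx, t, rtol=1e-7, atol=1e-9)
    for name in ("plasma_glucose", "plasma_insulin", "interstitial_glucose"):
        ya, yb = a.observable(name), b.observable(name)
        assert np.max(np.abs(ya - yb) / np.maximum(np.abs(yb), 1.0)) < 1e-5


def test_t_eval_validation(fixed, ctx, truth):
    with pytest.raises(ValueError):
        simulate(truth, fixed, ctx, np.array([5.0, 10.0]))
    with pytest.raises(ValueError):
        simulate(truth, fixed, ctx, np.array([0.0, 10.0, 10.0]))


def test_fixed_parameter_invariants():
    with pytest.raises(ValueError):
        FixedParameters(k2=-0.1)
    with pytest.raises(ValueError):
        FixedParameters(g_renal_threshold=5.0)


def test_fixed_parameters_yaml_roundtrip(tmp_path, fixed):
    path = tmp_path / "fixed.yaml"
    fixed.to_yaml(path)
    text = path.read_text()
    assert "mmol/L" in text  # units recorded in comments
    assert FixedParameters.from_yaml(path) == fixed
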