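"""Calibration tests: observation assembly, the normalized objective,
the multistart optimizer contract and fit diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import qmc

from edes import (CalibrationConfig, build_observations, fit_metrics,
                  objective, simulate, tiktak_calibrate)
from edes.calibration import (ObjectiveEvaluator, ObservationSet,
                              UnusableResponseError)


# ---------------------------------------------------------------- data


def test_build_observations_plasma_counts(noise_free_response):
    obs = build_observations(noise_free_response, "plasma")
    assert obs.glucose_times.size == 6 and obs.insulin_times.size == 6
    assert obs.glucose_times.min() > 0  # t = 0 is an input, not a point


def test_build_observations_cgm_counts(noise_free_response):
    obs = build_observations(noise_free_response, "cgm")
    assert obs.glucose_times.size == 26  # t = 5, 10, ..., 130
    assert obs.insulin_times.size == 6
    assert obs.glucose_times.min() == 5.0
    assert obs.glucose_times.max() == 130.0


def test_missing_cgm_trace_is_unusable(noise_free_response):
    resp = noise_free_response.replace(cgm_times=None, cgm_glucose=None)
    with pytest.raises(UnusableResponseError):
        build_observations(resp, "cgm")


def test_missing_samples_dropped(noise_free_response):
    glu = noise_free_response.plasma_glucose.copy()
    glu[2] = np.nan
    resp = noise_free_response.replace(plasma_glucose=glu)
    obs = build_observations(resp, "plasma")
    assert obs.glucose_times.size == 5 and obs.insulin_times.size == 6


# ----------------------------------------------------------- objective


def test_loss_single_metabolite_arithmetic():
    obs = ObservationSet("plasma", np.array([15.0, 30.0]),
                         np.array([2.0, 4.0]), np.array([]), np.array([]))
    assert obs.loss(np.array([3.0, 4.0]), np.array([])) == \
        pytest.approx(0.0625, abs=1e-15)


def test_loss_zero_for_exact_predictions(noise_free_response):
    obs = build_observations(noise_free_response, "plasma")
    assert obs.loss(obs.glucose_values, obs.insulin_values) == 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(min_value=0.1, max_value=1000.0))
def test_loss_scale_invariance(c):
    """Jointly rescaling a metabolite's data and predictions leaves the
    max-normalized loss unchanged."""
    y_g = np.array([5.0, 8.0, 6.0])
    p_g = np.array([5.5, 7.0, 6.2])
    y_i = np.array([10.0, 50.0, 30.0])
    p_i = np.array([12.0, 45.0, 33.0])
    t = np.array([15.0, 30.0, 60.0])
    base = ObservationSet("plasma", t, y_g, t, y_i).loss(p_g, p_i)
    scaled = ObservationSet("plasma", t, c * y_g, t, y_i).loss(c * p_g, p_i)
    assert scaled == pytest.approx(base, rel=1e-12)


def test_objective_matches_simulated_residuals(noise_free_response, fixed,
                                               truth):
    """objective() on the generating parameters is ~0 for noise-free data
    and positive elsewhere."""
    obs = build_observations(noise_free_response, "plasma")
    ctx = noise_free_response.context("plasma")
    at_truth = objective(truth.replace(tau_g=None), obs, fixed, ctx)
    off = objective(truth.replace(k1=0.03, tau_g=None), obs, fixed, ctx)
    assert at_truth < 1e-10 < off


def test_t0_points_rejected():
    with pytest.raises(ValueError):
        ObservationSet("plasma", np.array([0.0, 15.0]),
                       np.array([5.0, 6.0]), np.array([]), np.array([]))


# ----------------------------------------------------------- optimizer


def test_calibration_is_deterministic(noise_free_response, fixed):
    obs = build_observations(noise_free_response, "plasma")
    ctx = noise_free_response.context("plasma")
    config = CalibrationConfig(mode="plasma", seed=4, n_global=16,
                               n_local=2, local_maxfev=60, final_maxfev=60)
    a = tiktak_calibrate(obs, config, fixed, ctx)
    b = tiktak_calibrate(obs, config, fixed, ctx)
    assert a.estimates == b.estimates
    assert a.objective_value == b.objective_value


def test_multistart_never_worse_than_global_stage(noise_free_response,
                                                  fixed):
    """The returned optimum must dominate the best raw Sobol point."""
    obs = build_observations(noise_free_response, "plasma")
    ctx = noise_free_response.context("plasma")
    config = CalibrationConfig(mode="plasma", seed=9, n_global=32,
                               n_local=3, local_maxfev=80, final_maxfev=80)
    result = tiktak_calibrate(obs, config, fixed, ctx)
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    bounds = config.bounds()
    sob = qmc.Sobol(len(bounds), scramble=True,
                    rng=np.random.default_rng(config.seed))
    pts = bounds[:, 0] + (bounds[:, 1] - bounds[:, 0]) * sob.random(32)
    best_global = min(ev(p) for p in pts)
    assert result.objective_value <= best_global + 1e-12


def test_objective_value_is_recomputable(plasma_fit, fixed):
    fit, obs, config, ctx = plasma_fit
    theta = [getattr(fit.estimates, p) for p in config.param_names]
    ev = ObjectiveEvaluator(obs, fixed, ctx, config)
    assert ev(theta) == pytest.approx(fit.objective_value, abs=1e-9)


def test_boundary_hit_flagged_for_out_of_box_truth(noise_free_response,
                                                   fixed, ctx, truth):
    """Data generated beyond the k6 search bound drives the estimate onto
    the bound, which must be flagged."""
    grid = np.arange(0.0, 121.0, 15.0)
    # k6 beyond the search bound, k5 lowered so the trajectory stays
    # physiological despite the large secretion gain
    big = truth.replace(k6=11.0, k5=0.004, tau_g=None)
    tr = simulate(big, fixed, ctx, grid)
    obs = ObservationSet("plasma", grid[1:], tr.plasma_glucose[1:],
                         grid[1:], tr.plasma_insulin[1:])
    config = CalibrationConfig(mode="plasma", seed=2, n_global=32,
                               n_local=4)
    fit = tiktak_calibrate(obs, config, fixed, ctx)
    assert fit.boundary_hit["k6"]
    assert fit.estimates.k6 == pytest.approx(10.0, abs=1e-9)


def test_all_simulations_failing_yields_penalty_result(
        noise_free_response, fixed, monkeypatch):
    import edes.calibration as cal

    def boom(*a, **kw):
        raise cal.SimulationError("forced failure")

    monkeypatch.setattr(cal, "simulate", boom)
    obs = build_observations(noise_free_response, "plasma")
    ctx = noise_free_response.context("plasma")
    config = CalibrationConfig(mode="plasma", seed=1, n_global=8, n_local=2,
                               local_maxfev=20, final_maxfev=20)
    fit = tiktak_calibrate(obs, config, fixed, ctx)
    assert not fit.success
    assert fit.objective_value >= config.penalty
    assert all(fit.boundary_hit.values())


# ----------------------------------------------------------- metrics


def test_fit_metrics_perfect_fit(plasma_fit, fixed):
    fit, obs, config, ctx = plasma_fit
    mse, table = fit_metrics(fit, obs, fixed, ctx)
    assert mse["glucose"] == pytest.approx(0.0, abs=1e-8)
    assert mse["insulin"] == pytest.approx(0.0, abs=1e-6)
    # MSE recomputed from the stored residuals equals the stored MSE
    for name in ("glucose", "insulin"):
        r = table.loc[table.observable == name, "residual"].to_numpy()
        assert np.mean(r ** 2) == pytest.approx(mse[name], rel=1e-12)


def test_mse_definition_on_known_residuals():
    """Glucose residuals (+1, -1) over two points give MSE 1 (mmol/L)^2."""
    t = np.array([15.0, 30.0])
    obs = ObservationSet("plasma", t, np.array([6.0, 8.0]),
                         np.array([]), np.array([]))
    pred = np.array([5.0, 9.0])
    res = obs.glucose_values - pred
    assert np.mean(res ** 2) == 1.0
    assert obs.loss(pred, np.array([])) == pytest.approx(2 / 64, rel=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        CalibrationConfig(mode="plasma", ranges={"k1": (1.0, 0.5),
                                                 "k5": (0.0, 1.0),
                                                 "k6": (0.0, 1.0)})
    with pytest.raises(ValueError):
        CalibrationConfig(mode="nope")
    with pytest.raises(ValueError):
        CalibrationConfig(n_global=0)
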