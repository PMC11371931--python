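import numpy as np
import pytest

from edes import (CGM_DESIGN_TIMES, OGTT_DESIGN_TIMES, CalibrationConfig,
                  EstimableParameters, FixedParameters, SubjectContext,
                  SubjectResponse, build_observations, simulate,
                  tiktak_calibrate)

from edes.synthetic_data import NoiseModel

#: ground truth used by the deterministic single-subject fixtures
TRUTH = EstimableParameters(k1=0.016, k5=0.04, k6=0.9, tau_g=3.0)

#: a noise model with every component switched off
NOISE_FREE = NoiseModel(plasma_glucose_cv=0.0, insulin_cv=0.0,
                        cgm_proportional_cv=0.0, cgm_bias_mean=0.0,
                        cgm_bias_sd=0.0)


@pytest.fixture(scope="session")
def fixed():
    return FixedParameters()


@pytest.fixture(scope="session")
def ctx():
    return SubjectContext(body_mass=85.0, glucose_dose=75.0,
                          basal_plasma_glucose=5.3, basal_insulin=11.0)


@pytest.fixture(scope="session")
def truth():
    return TRUTH


@pytest.fixture(scope="session")
def noise_free_response(fixed, ctx, truth):
    """A complete OGTT+CGM response sampled exactly from the model."""
    grid = np.union1d(OGTT_DESIGN_TIMES, CGM_DESIGN_TIMES)
    tr = simulate(truth, fixed, ctx, grid)
    gi = np.searchsorted(grid, OGTT_DESIGN_TIMES)
    ci = np.searchsorted(grid, CGM_DESIGN_TIMES)
    return SubjectResponse(
        subject_id="nf", visit="baseline",
        ogtt_times=OGTT_DESIGN_TIMES.copy(),
        plasma_glucose=tr.plasma_glucose[gi],
        plasma_insulin=tr.plasma_insulin[gi],
        cgm_times=CGM_DESIGN_TIMES.copy(),
        cgm_glucose=tr.interstitial_glucose[ci],
        body_mass=ctx.body_mass, glucose_dose=ctx.glucose_dose)


@pytest.fixture(scope="session")
def plasma_fit(noise_free_response, fixed):
    """A converged plasma-mode fit of the noise-free response (reduced
    multistart budget: the optimum is unique and easy to find)."""
    obs = build_observations(noise_free_response, "plasma")
    config = CalibrationConfig(mode="plasma", seed=11, n_global=64,
                               n_local=6)
    context = noise_free_response.context("plasma")
    fit = tiktak_calibrate(obs, config, fixed, context)
    return fit, obs, config, context
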