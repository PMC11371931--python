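"""Synthetic cohort generator: reproducibility, the noise model,
missingness injection and the exclusion rules."""

import numpy as np
import pytest

from edes import (CGM_DESIGN_TIMES, OGTT_DESIGN_TIMES, SubjectResponse,
                  apply_exclusions, cohort_truth, generate_cohort,
                  inject_missingness, sample_subject)
from edes.synthetic_data import (CohortSpec, LogNormalSpec, NoiseModel,
                                 REASON_IRREGULAR_CGM,
                                 REASON_MISSING_BASELINE,
                                 REASON_MISSING_CHANNEL,
                                 REASON_MISSING_TWO_HOUR,
                                 REASON_TOO_MANY_MISSING)

from conftest import NOISE_FREE


def test_same_seed_same_cohort(fixed):
    spec = CohortSpec(n_subjects=4)
    a = generate_cohort(spec, seed=5, fixed=fixed)
    b = generate_cohort(spec, seed=5, fixed=fixed)
    for sa, sb in zip(a, b):
        assert sa.true_parameters == sb.true_parameters
        assert np.array_equal(sa.response.plasma_glucose,
                              sb.response.plasma_glucose)
        assert np.array_equal(sa.response.cgm_glucose,
                              sb.response.cgm_glucose)


def test_zero_noise_samples_equal_clean_trajectory(fixed):
    spec = CohortSpec(n_subjects=2, noise=NOISE_FREE)
    subj = generate_cohort(spec, seed=1, fixed=fixed)[0]
    grid = np.union1d(spec.ogtt_times, spec.cgm_times)
    gi = np.searchsorted(grid, spec.ogtt_times)
    ci = np.searchsorted(grid, spec.cgm_times)
    assert np.array_equal(subj.response.plasma_glucose,
                          subj.clean.plasma_glucose[gi])
    assert np.array_equal(subj.response.cgm_glucose,
                          subj.clean.interstitial_glucose[ci])


def test_clean_trajectory_regenerates_from_truth(fixed):
    from edes import simulate
    subj = generate_cohort(CohortSpec(n_subjects=1), seed=8, fixed=fixed)[0]
    grid = subj.clean.times
    again = simulate(subj.true_parameters, fixed, subj.context, grid,
                     keep_states=False)
    assert np.allclose(subj.clean.plasma_glucose, again.plasma_glucose)


def test_long_lag_delays_cgm_peak(fixed):
    dists = CohortSpec().distributions
    dists = {**dists, "tau_g": LogNormalSpec(10.0, 0.0)}  # fixed 10 min
    spec = CohortSpec(n_subjects=1, distributions=dists,
                      noise=NOISE_FREE)
    subj = sample_subject(spec, np.random.default_rng(2), fixed)
    clean = subj.clean
    t = clean.times
    assert t[np.argmax(clean.interstitial_glucose)] >= \
        t[np.argmax(clean.plasma_glucose)]


def test_cgm_runs_above_plasma_on_average(fixed):
    """The measured cohort reproduces the qualitative CGM-vs-plasma
    pattern: interstitial readings run above plasma glucose (systematic
    sensor offset) with a delayed peak, so the cohort-median CGM AUC over
    the shared window is at least the median plasma AUC."""
    subs = generate_cohort(CohortSpec(n_subjects=12), seed=4, fixed=fixed)
    cgm_auc, pl_auc = [], []
    for s in subs:
        r = s.response
        w = r.cgm_times <= 120.0
        cgm_auc.append(np.trapezoid(r.cgm_glucose[w], r.cgm_times[w]))
        pl_auc.append(np.trapezoid(r.plasma_glucose, r.ogtt_times))
    assert np.median(cgm_auc) >= np.median(pl_auc)


def test_missingness_probability_zero_is_identity(fixed):
    spec = CohortSpec(n_subjects=1)
    subj = generate_cohort(spec, seed=3, fixed=fixed)[0]
    out = inject_missingness(subj, spec, np.random.default_rng(0))
    assert np.array_equal(out.plasma_glucose, subj.response.plasma_glucose)
    assert np.array_equal(out.cgm_times, subj.response.cgm_times)


def test_missingness_rate_matches_probability(fixed):
    """Monte-Carlo removal rate within 3 sigma of the binomial at
    n = 1000 sampling slots."""
    p = 0.3
    n_slots = 1000
    resp = SubjectResponse("mc", "b", np.linspace(0.0, 999.0, n_slots),
                           np.full(n_slots, 6.0), np.full(n_slots, 20.0),
                           CGM_DESIGN_TIMES.copy(),
                           np.full(CGM_DESIGN_TIMES.size, 6.0), 80.0)
    subj = generate_cohort(CohortSpec(n_subjects=1), seed=6, fixed=fixed)[0]
    subj.response = resp
    spec = CohortSpec(n_subjects=1, plasma_missing_prob=p)
    out = inject_missingness(subj, spec, np.random.default_rng(12))
    removed = int(np.isnan(out.plasma_glucose).sum())
    sigma = np.sqrt(n_slots * p * (1 - p))
    assert abs(removed - n_slots * p) <= 3 * sigma


def _complete_response():
    n = OGTT_DESIGN_TIMES.size
    return SubjectResponse("x", "b", OGTT_DESIGN_TIMES.copy(),
                           np.full(n, 6.0), np.full(n, 20.0),
                           CGM_DESIGN_TIMES.copy(),
                           np.full(CGM_DESIGN_TIMES.size, 6.5), 80.0)


def test_exclusion_rules_boundary_cases():
    complete = _complete_response()

    # two missing interior samples: still kept
    two_gone = _complete_response()
    two_gone.plasma_glucose[[1, 3]] = np.nan
    two_gone.plasma_insulin[[1, 3]] = np.nan

    # three missing interior samples: excluded
    three_gone = _complete_response()
    three_gone.plasma_glucose[[1, 3, 4]] = np.nan
    three_gone.plasma_insulin[[1, 3, 4]] = np.nan

    # missing baseline / missing 2-hour draws
    no_t0 = _complete_response()
    no_t0.plasma_glucose[0] = np.nan
    no_t0.plasma_insulin[0] = np.nan
    no_2h = _complete_response()
    no_2h.plasma_glucose[-1] = np.nan

    # irregular CGM grid and missing CGM channel
    irregular = _complete_response()
    keep = np.ones(irregular.cgm_times.size, dtype=bool)
    keep[4] = False
    irregular.cgm_times = irregular.cgm_times[keep]
    irregular.cgm_glucose = irregular.cgm_glucose[keep]
    no_cgm = _complete_response().replace(cgm_times=None, cgm_glucose=None)

    kept, excluded = apply_exclusions(
        [complete, two_gone, three_gone, no_t0, no_2h, irregular, no_cgm])
    assert any(r is complete for r in kept)
    assert any(r is two_gone for r in kept)
    by_resp = {id(r): rs for r, rs in excluded}
    assert REASON_TOO_MANY_MISSING in by_resp[id(three_gone)]
    assert REASON_MISSING_BASELINE in by_resp[id(no_t0)]
    assert REASON_MISSING_TWO_HOUR in by_resp[id(no_2h)]
    assert REASON_IRREGULAR_CGM in by_resp[id(irregular)]
    assert REASON_MISSING_CHANNEL in by_resp[id(no_cgm)]


def test_truth_table_shape(fixed):
    subs = generate_cohort(CohortSpec(n_subjects=3), seed=9, fixed=fixed)
    truth = cohort_truth(subs)
    assert list(truth.columns) == ["subject_id", "visit", "k1", "k5",
                                   "k6", "tau_g"]
    assert len(truth) == 3
    assert (truth[["k1", "k5", "k6", "tau_g"]] > 0).all().all()


def test_lognormal_spec_clipping():
    d = LogNormalSpec(5.0, 2.0, lower=1.0, upper=10.0)
    rng = np.random.default_rng(0)
    draws = np.array([d.draw(rng) for _ in range(200)])
    assert draws.min() >= 1.0 and draws.max() <= 10.0


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=0)
    with pytest.raises(ValueError):
        CohortSpec(plasma_missing_prob=1.5)
    with pytest.raises(ValueError):
        NoiseModel(plasma_glucose_cv=-0.1)
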