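"""Model/Results interface for fitting one response.

`GlucoseInsulinModel` wraps a measured response plus a calibration mode;
`fit()` runs the multistart calibration and returns a
`GlucoseInsulinResults` carrying the estimates, fit diagnostics, and
methods for profile likelihood, confidence bands, simulation and plotting.

    >>> model = GlucoseInsulinModel(response, mode="cgm")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> curve = res.profile("k5")
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (CalibrationConfig, build_observations,
                          tiktak_calibrate)
from .data import OGTT_DESIGN_TIMES, SubjectResponse
from .identifiability import (identifiability_report, observable_band,
                              profile_parameter)
from .model_core import simulate
from .params import FixedParameters

__all__ = ["GlucoseInsulinModel", "GlucoseInsulinResults"]


class GlucoseInsulinModel:
    """Personalized glucose-insulin model for one measured response.

    Parameters
    ----------
    response : SubjectResponse
        The measured OGTT plasma series (and CGM trace in cgm mode).
    mode : {"plasma", "cgm"}
        Which glucose channel is fitted; plasma insulin is always fitted.
    fixed : FixedParameters, optional
        Population-level constants (defaults used when omitted).
    config : CalibrationConfig, optional
        Search box and multistart budget.
    """

    def __init__(self, response: SubjectResponse, mode: str = "plasma",
                 fixed: FixedParameters | None = None,
                 config: CalibrationConfig | None = None):
        self.response = response
        self.mode = mode
        self.fixed = fixed if fixed is not None else FixedParameters()
        self.config = (config if config is not None
                       else CalibrationConfig(mode=mode)).replace(mode=mode)
        self.observations = build_observations(response, mode)
        self.context = response.context(mode)

    @classmethod
    def from_dataframes(cls, ogtt: pd.DataFrame, context_row: dict,
                        cgm: pd.DataFrame | None = None,
                        mode: str = "plasma", **kw) -> "GlucoseInsulinModel":
        """Build from the standard CSV schemas already loaded as frames.

        ``ogtt`` needs columns time_min, plasma_glucose_mmol_per_L,
        plasma_insulin_mU_per_L; ``cgm`` time_min,
        interstitial_glucose_mmol_per_L; ``context_row`` the keys
        subject_id, visit, body_mass_kg and dose_g.
        """
        glu = np.full(OGTT_DESIGN_TIMES.size, np.nan)
        ins = np.full(OGTT_DESIGN_TIMES.size, np.nan)
        for t, g, i in zip(ogtt["time_min"],
                           ogtt["plasma_glucose_mmol_per_L"],
                           ogtt["plasma_insulin_mU_per_L"]):
            j = np.flatnonzero(np.isclose(OGTT_DESIGN_TIMES, t))
            if j.size:
                glu[j[0]], ins[j[0]] = g, i
        response = SubjectResponse(
            subject_id=str(context_row["subject_id"]),
            visit=str(context_row.get("visit", "baseline")),
            ogtt_times=OGTT_DESIGN_TIMES.copy(),
            plasma_glucose=glu, plasma_insulin=ins,
            cgm_times=None if cgm is None else cgm["time_min"].to_numpy(float),
            cgm_glucose=(None if cgm is None
                         else cgm["interstitial_glucose_mmol_per_L"]
                         .to_numpy(float)),
            body_mass=float(context_row["body_mass_kg"]),
            glucose_dose=float(context_row.get("dose_g", 75.0)))
        return cls(response, mode=mode, **kw)

    def fit(self, seed: int | None = None) -> "GlucoseInsulinResults":
        """Run the TikTak multistart calibration."""
        config = self.config if seed is None else self.config.replace(seed=seed)
        result = tiktak_calibrate(self.observations, config,
                                  self.fixed, self.context)
        return GlucoseInsulinResults(self, result, config)

    def simulate(self, estimables, t_eval=None):
        if t_eval is None:
            t_eval = np.arange(0.0, 131.0, 1.0)
        return simulate(estimables, self.fixed, self.context, t_eval)


class GlucoseInsulinResults:
    """Fit results: estimates, diagnostics, uncertainty analyses."""

    def __init__(self, model: GlucoseInsulinModel, calibration, config):
        self.model = model
        self.calibration = calibration
        self.config = config

    # --- convenience accessors -----------------------------------------
    @property
    def params(self) -> pd.Series:
        d = {k: v for k, v in self.calibration.estimates.to_dict().items()
             if v is not None}
        return pd.Series(d, name="estimate")

    @property
    def objective(self) -> float:
        return self.calibration.objective_value

    @property
    def mse(self) -> dict:
        return self.calibration.mse

    @property
    def residuals(self) -> pd.DataFrame:
        return self.calibration.residual_table

    @property
    def boundary_hit(self) -> dict:
        return self.calibration.boundary_hit

    # --- uncertainty ----------------------------------------------------
    def profile(self, which: str, alpha: float = 0.95, **kw):
        """Profile-likelihood curve and CI of one parameter."""
        return profile_parameter(self.calibration, self.model.observations,
                                 self.model.fixed, self.model.context,
                                 which, config=self.config, alpha=alpha, **kw)

    def identifiability(self, alpha: float = 0.95):
        """Profile k1, k5, k6 and classify practical identifiability."""
        return identifiability_report(self.calibration,
                                      self.model.observations,
                                      self.model.fixed, self.model.context,
                                      config=self.config, alpha=alpha)

    def confidence_band(self, observable: str, times=None,
                        alpha: float = 0.95):
        if times is None:
            times = np.arange(0.0, 131.0, 5.0)
        return observable_band(self.calibration, self.model.observations,
                               self.model.fixed, self.model.context,
                               observable, times, alpha=alpha,
                               config=self.config)

    def simulate(self, t_eval=None):
        return self.model.simulate(self.calibration.estimates, t_eval)

    # --- presentation ---------------------------------------------------
    def summary(self) -> str:
        c = self.calibration
        lines = [
            "Personalized glucose-insulin model fit",
            "=" * 54,
            f"subject/visit      {self.model.response.key}",
            f"glucose channel    {c.mode}",
            f"objective L(theta) {c.objective_value:.6g}",
            f"MSE glucose        {c.mse.get('glucose', float('nan')):.4g} (mmol/L)^2",
            f"MSE insulin        {c.mse.get('insulin', float('nan')):.4g} (mU/L)^2",
            f"local optima conv. {c.n_local_converged}/{self.config.n_local}",
            "-" * 54,
            f"{'parameter':<10}{'estimate':>14}{'boundary':>10}",
        ]
        for name, value in self.params.items():
            hit = "yes" if c.boundary_hit.get(name) else ""
            lines.append(f"{name:<10}{value:>14.6g}{hit:>10}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data and fitted trajectories for glucose and insulin."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        traj = self.simulate()
        obs = self.model.observations
        glu_name = ("interstitial_glucose" if obs.glucose_source == "cgm"
                    else "plasma_glucose")
        ax[0].plot(traj.times, traj.observable(glu_name), "-",
                   label="model")
        ax[0].plot(obs.glucose_times, obs.glucose_values, "o", label="data")
        ax[0].set_ylabel(f"{obs.glucose_source} glucose (mmol/L)")
        ax[0].legend()
        ax[1].plot(traj.times, traj.plasma_insulin, "-")
        ax[1].plot(obs.insulin_times, obs.insulin_values, "o")
        ax[1].set_ylabel("plasma insulin (mU/L)")
        ax[1].set_xlabel("time (min)")
        return ax
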