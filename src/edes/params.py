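"""Model parameters and subject context.

The glucose-insulin model separates its parameters into three groups:

* :class:`FixedParameters` -- population-level rate constants and physical
  constants that are held fixed during per-subject calibration,
* :class:`EstimableParameters` -- the per-subject quantities recovered by
  calibration (``k1``, ``k5``, ``k6`` and, when fitting CGM data, ``tau_g``),
* :class:`SubjectContext` -- measured per-subject inputs (body mass, glucose
  dose, basal concentrations) that parameterize the simulation but are never
  optimized.

All glucose concentrations are mmol/L, insulin mU/L, time minutes and the
meal dose grams, so that parameter values can be read directly against
clinical numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields

import yaml

__all__ = [
    "FixedParameters",
    "EstimableParameters",
    "SubjectContext",
]


@dataclass(frozen=True)
class FixedParameters:
    """Non-estimated rate constants and physical constants.

    The defaults are population-scale values chosen to produce physiological
    oral-glucose-tolerance responses (glucose peak of roughly 8--9 mmol/L near
    30--45 min returning toward basal by 120 min, insulin peaking at several
    times basal) for an adult with overweight; they are the reference point
    around which per-subject calibration moves the estimable parameters.

    Parameters
    ----------
    k2 : float
        Gut emptying rate constant (1/min): transfer of gut glucose to plasma.
    sigma : float
        Dimensionless shape of the Weibull-form glucose appearance into the
        gut after a drink; values > 1 delay the appearance peak.
    f_bio : float
        Bioavailable fraction of the ingested glucose dose (dimensionless).
        A pure glucose drink is taken as fully absorbed.
    egp_basal : float
        Basal endogenous (hepatic) glucose production expressed as a plasma
        concentration flux (mmol/L/min).
    k3 : float
        Suppression of endogenous production per unit glucose elevation above
        basal (1/min).
    k4 : float
        Suppression of endogenous production per unit remote insulin action
        ((mmol/L/min) per (mU/L)).
    km : float
        Michaelis constant of tissue glucose uptake (mmol/L).
    g_renal_threshold : float
        Plasma glucose above which renal excretion starts (mmol/L).
    renal_clearance : float
        Renal clearance rate of glucose above the threshold (L/min).
    k7 : float
        Integral gain of glucose-driven insulin secretion (dimensionless,
        applied as ``k7 / tau_i`` on the accumulated glucose elevation).
    k8 : float
        Derivative gain of glucose-driven insulin secretion (dimensionless,
        applied as ``k8 * tau_d`` on dG/dt).
    tau_i, tau_d : float
        Time constants (min) of the integral and derivative secretion terms.
    k9 : float
        Appearance rate of plasma insulin into the remote (interstitial
        action) compartment (1/min).
    k10 : float
        Decay rate of remote insulin action (1/min).
    insulin_clearance : float
        First-order clearance of plasma insulin above basal (1/min); basal
        secretion and clearance are folded together so basal insulin is a
        steady state.
    v_g : float
        Glucose distribution volume per body mass (L/kg).
    beta : float
        Unit conversion between the insulin scale (mU/L) and the glucose
        scale (mmol/L) in the secretion and action terms.
    f_conv : float
        mmol of glucose per mg (1/180.16 molar mass).
    """

    k2: float = 0.28
    sigma: float = 1.34
    f_bio: float = 1.0
    egp_basal: float = 0.043
    k3: float = 0.006
    k4: float = 5.0e-4
    km: float = 13.2
    g_renal_threshold: float = 9.0
    renal_clearance: float = 0.1
    k7: float = 0.02
    k8: float = 1.0
    tau_i: float = 31.0
    tau_d: float = 3.0
    k9: float = 0.03
    k10: float = 0.06
    insulin_clearance: float = 0.07
    v_g: float = 17.0 / 70.0
    beta: float = 1.0
    f_conv: float = 1.0 / 180.16

    # units recorded alongside each symbol when serializing
    _UNITS = {
        "k2": "1/min",
        "sigma": "dimensionless",
        "f_bio": "dimensionless fraction",
        "egp_basal": "mmol/L/min",
        "k3": "1/min",
        "k4": "(mmol/L/min) per (mU/L)",
        "km": "mmol/L",
        "g_renal_threshold": "mmol/L",
        "renal_clearance": "L/min",
        "k7": "dimensionless",
        "k8": "dimensionless",
        "tau_i": "min",
        "tau_d": "min",
        "k9": "1/min",
        "k10": "1/min",
        "insulin_clearance": "1/min",
        "v_g": "L/kg",
        "beta": "(mU/L) per (mmol/L)",
        "f_conv": "mmol/mg",
    }

    def __post_init__(self) -> None:
        for name in ("k2", "egp_basal", "km", "v_g", "beta", "f_conv",
                     "tau_i", "tau_d", "insulin_clearance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fixed parameter {name!r} must be positive")
        for name in ("k3", "k4", "k7", "k8", "k9", "k10",
                     "renal_clearance", "f_bio"):
            if getattr(self, name) < 0:
                raise ValueError(f"fixed parameter {name!r} must be >= 0")
        if self.g_renal_threshold < 7.0:
            raise ValueError(
                "renal threshold must exceed physiological basal glucose "
                "(>= 7 mmol/L)")

    def replace(self, **kw) -> "FixedParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        """Write a key-value config file with the unit of each symbol."""
        lines = ["# fixed model parameters (units in trailing comments)\n"]
        for f in fields(self):
            val = getattr(self, f.name)
            lines.append(f"{f.name}: {val!r}  # {self._UNITS[f.name]}\n")
        with open(path, "w") as fh:
            fh.writelines(lines)

    @classmethod
    def from_yaml(cls, path) -> "FixedParameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class EstimableParameters:
    """Per-subject parameters recovered by calibration.

    ``k1`` is the rate of glucose appearance in the gut (1/min), ``k5`` the
    rate of insulin-dependent glucose uptake into peripheral tissue
    ((mmol/L/min) per (mU/L) at glucose saturation), ``k6`` the dimensionless
    gain of glucose-dependent insulin secretion, and ``tau_g`` the
    plasma-to-interstitium equilibration time constant (min).  ``tau_g`` only
    matters when interstitial (CGM) glucose is simulated or fitted; ``None``
    or ``0`` means the interstitial trace equals plasma glucose identically.
    """

    k1: float
    k5: float
    k6: float
    tau_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"estimable parameter {name!r} must be >= 0")
        if self.tau_g is not None and self.tau_g < 0:
            raise ValueError("tau_g must be >= 0")

    def replace(self, **kw) -> "EstimableParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


#: population-scale default estimable parameters (the synthetic cohort is
#: drawn around these; tau_g centered on a 2.5 min median lag)
DEFAULT_ESTIMABLES = EstimableParameters(k1=0.015, k5=0.035, k6=0.8, tau_g=2.5)


@dataclass(frozen=True)
class SubjectContext:
    """Measured per-subject simulation inputs.

    Basal (t = 0) values are model inputs, not fitted observations.  When no
    separate basal interstitial glucose is available the plasma basal is used
    for the interstitial compartment as well.
    """

    body_mass: float                    # kg
    glucose_dose: float                 # g
    basal_plasma_glucose: float         # mmol/L
    basal_insulin: float                # mU/L
    basal_interstitial_glucose: float | None = None  # mmol/L

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.glucose_dose < 0:
            raise ValueError("glucose_dose must be >= 0")
        if self.basal_plasma_glucose <= 0 or self.basal_insulin <= 0:
            raise ValueError("basal concentrations must be strictly positive")
        if (self.basal_interstitial_glucose is not None
                and self.basal_interstitial_glucose <= 0):
            raise ValueError("basal interstitial glucose must be positive")

    @property
    def interstitial_basal(self) -> float:
        """Basal interstitial glucose, falling back to the plasma basal."""
        if self.basal_interstitial_glucose is None:
            return self.basal_plasma_glucose
        return self.basal_interstitial_glucose

    def replace(self, **kw) -> "SubjectContext":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
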