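# edes — personalized glucose–insulin models from OGTT or CGM data

`edes` builds *personalized* models of insulin-regulated glucose
metabolism for people undergoing an oral glucose tolerance test (OGTT),
and asks a practical question of growing clinical relevance: **can
minimally invasive interstitial glucose from a CGM sensor replace plasma
glucose in calibrating such models?** It is aimed at researchers in
metabolic physiology, precision nutrition and diabetes prevention who
work with OGTT and sensor data.

The core is an E-DES-family compartmental ODE model (gut, plasma
glucose, plasma insulin, remote insulin action) extended with an
interstitial compartment

dG<sup>i</sup>/dt = (G<sup>pl</sup> − G<sup>i</sup>)/τ<sub>g</sub>,

so the same model can be fitted to either glucose source. Per subject,
calibration estimates the rate of glucose appearance in the gut
(k₁), the rate of insulin-dependent glucose uptake (k₅, an
insulin-sensitivity measure), the gain of glucose-dependent insulin
secretion (k₆) and — when fitting CGM data — the plasma-to-interstitium
lag τ<sub>g</sub>, by minimizing the max-normalized least squares

L(θ) = Σ<sub>i</sub> Σ<sub>j</sub> ((y<sub>ij</sub> − ŷ<sub>ij</sub>(θ)) / max(**y**<sub>i</sub>))²

with a TikTak multistart (Sobol global stage + blended Nelder–Mead
polishes). Practical identifiability is assessed by profile likelihood,
uncertainty in predictions by profile-based confidence bands, and the
estimates are validated against classical metabolic indicators (Matsuda,
HOMA-IR/β, MISI, HIRI, insulinogenic and disposition indices). A
synthetic-cohort generator with known ground truth emulates the paired
OGTT + CGM design, sensor noise and lag, missing samples and the
standard exclusion rules, so the whole plasma-vs-CGM comparison workflow
runs end to end without access-restricted clinical data. See
[docs/methods.md](docs/methods.md) for the model equations, defaults and
conventions.

## Worked example

Generate one synthetic subject and fit the CGM-mode model:

```python
from edes import CohortSpec, FixedParameters, GlucoseInsulinModel, generate_cohort

fixed = FixedParameters()
subject = generate_cohort(CohortSpec(n_subjects=1), seed=7, fixed=fixed)[0]
model = GlucoseInsulinModel(subject.response, mode="cgm", fixed=fixed)
result = model.fit(seed=1)
print(result.summary())
```

```
Personalized glucose-insulin model fit
======================================================
subject/visit      s000_baseline
glucose channel    cgm
objective L(theta) 0.0421847
MSE glucose        0.09947 (mmol/L)^2
MSE insulin        4.035 (mU/L)^2
local optima conv. 12/16
------------------------------------------------------
parameter       estimate  boundary
k1             0.0151322
k5             0.0448478
k6              0.604221
tau_g           0.450116
======================================================
```

This subject was generated with k₁ = 0.01501, k₅ = 0.04064, k₆ = 0.7169
and τ<sub>g</sub> = 0.503 min: the appearance and uptake rates are
recovered to within a few percent from noisy sensor data, the secretion
gain and sub-minute lag less sharply — exactly the pattern the
identifiability analysis quantifies. The glucose MSE of 0.099 (mmol/L)²
means the fitted trajectory tracks the 26 sensor readings to about
±0.3 mmol/L. From here, `result.profile("k5")` returns the profile
likelihood with its 95% confidence interval, `result.identifiability()`
classifies the fit, and `result.confidence_band("glucose")` gives the
prediction band; `result.plot_fit()` draws data and trajectories.

The same workflow scales to cohorts (`run_cohort`, `build_report`) and
is scriptable from the shell:

```bash
edes generate --n-subjects 20 --seed 0 --out data/
edes calibrate data/ --mode both --seed 0 --out results/
edes indicators data/ --out indicators.csv
edes report data/ results/ --out report/
```

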