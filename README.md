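# eggdrift

Diffusion–mortality modelling of fish-egg dispersal from a spawning
aggregation, built for plankton-survey data collected around drogued
drifters.

Many overfished reef fish (Nassau grouper is the motivating case) release
their entire annual reproductive output at a handful of transient spawning
aggregations. Whether the resulting larvae are retained near the natal reef
or exported elsewhere determines the spatial scale at which protection
works — yet the two rates that control the answer, horizontal diffusivity
and early-life mortality, are rarely measured in the field. `eggdrift`
estimates both from towed-imaging egg counts taken around drifters released
into the egg plume, and then applies the fitted rates to other years'
drifter tracks to predict retention versus export.

## Model

Working in the drifter-centroid frame removes advection. The egg
concentration is separable,

```
C(x, y, z, t) = C(z, t) · C(x, y, t)
```

* **Vertical** `C(z, t)`: a drift-corrected random walk (Visser scheme) of
  10 000 particles under depth-decaying turbulent diffusivity
  `K_z(z) = K0·exp(−z/z_MLD)`, with reflective surface and optional egg
  buoyancy `w_s`; the particle cloud is reduced to a normalized density by
  a boundary-reflected 2-D kernel density estimate.
* **Horizontal** `C(x, y, t)`: the anisotropic Fickian point-release
  solution with constant mortality,

  ```
  C(x, y, t) = exp(−x²/(4·Kx·t) − y²/(4·Ky·t) − μ·t) / (4π·t·√(Kx·Ky))
  ```

* **Observation model**: per-minute egg counts `Y_i` at tow positions
  `(x_i, y_i, z_i, t_i)` are negative-binomial with mean
  `e^β · C(x_i, y_i, z_i, t_i)` (volume sampled per minute, 264 l, as
  exposure) and overdispersion `k`. Maximum likelihood gives `Kx, Ky, μ, β,
  k`; uncertainty comes from likelihood profiles, submodels are compared by
  AIC.

Downstream, annual egg production (mature abundance × sex ratio ×
fecundity-at-length, allocated 40/40/10/10 across spawning nights) scales
the fitted kernel into predicted plume maps around arbitrary drifter
tracks, with stage-structured mortality (fitted egg rate to hatching at
24 h, a lower yolk-sac-larva rate to 4 days post hatch).

A synthetic-survey generator (correlated-velocity drifter, undulating
1–30 m tow at ~3 cycles km⁻¹, NB counts from the model) makes every stage
testable end-to-end without field data.

## Worked example

```python
from eggdrift import SyntheticConfig, simulate_survey, EggDispersalModel, ModelSpec

cfg = SyntheticConfig(seed=1)          # 15 h survey at the default true rates
ds = simulate_survey(cfg)
model = EggDispersalModel(ds.observations, ds.vertical, ModelSpec.full())
res = model.fit(seed=0)
print(res.summary(conf_int=True))
print(f"deviance explained: {res.deviance_explained():.3f}")
```

```
Egg dispersal model (negative binomial ML)
  submodel: full    nobs: 871
  log-likelihood: -279.124    AIC: 568.249
  converged: True    max|grad|: 5.28e-05

  param      estimate        lower        upper
  beta         19.207       18.687       20.038
  Kx            14047       9698.2        22635
  Ky            35707        19214   2.2968e+05
  mu          0.19477      0.11967      0.27794
  k           0.41033      0.26909      0.63158
deviance explained: 0.681
```

The survey was generated with true `Kx = 14 900`, `Ky = 49 100` m² h⁻¹ and
`μ = 0.172` h⁻¹: the fit recovers the east–west diffusivity and the
mortality rate well within their 95% profile intervals (`Ky`, sampled along
fewer north–south transect metres, is the least precise). `μ = 0.172` h⁻¹
corresponds to 4.13 day⁻¹, i.e. ~1.6% of eggs survive the 24 h to hatching
— survival that the prediction module carries forward with the reduced
larval rate when mapping plumes around drifter tracks.

A thin CLI mirrors the library (`eggdrift simulate|fit|predict|production|
vertical-simulate|tracks-centroid`).

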