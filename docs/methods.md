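# Methods

## Model and assumptions

`eggdrift` models the concentration of pelagic fish eggs released as an
instantaneous point source at a spawning aggregation, observed around
drogued drifters that mark the advective frame. The model assumes:

* the drifters capture horizontal advection and there is no vertical
  current shear, so subtracting the drifter-centroid position removes the
  advective terms entirely;
* seawater is incompressible and mortality is constant in space and time
  over the egg stage;
* vertical and horizontal diffusion are separable,
  `C(x,y,z,t) = C(z,t)·C(x,y,t)`, with the vertical factor normalized to
  unit integral at every time so that mortality and horizontal spread are
  carried by the horizontal factor alone;
* horizontal diffusion is Fickian with constant, axis-aligned anisotropic
  diffusivities (justified when the patch size varies by less than an
  order of magnitude over the observation window; no principal-axis
  rotation is estimated);
* eggs and yolk-sac larvae are passive; predictions stop at 4 days post
  hatch, before swim bladder and fins can influence transport.

Time zero is 19.00 local on the spawning night; all model times are hours
since release. Depth is metres, positive down, surface at z = 0.

## Vertical random walk

Spatially varying diffusivity requires the drift-corrected (Visser)
update; a naive walk unphysically concentrates particles where `K_z` is
small. Each step of `Δt = 10 s` is

```
z' = z + K_z'(z)·Δt + R·sqrt(2·K_z(z + ½K_z'(z)Δt)·Δt / r) + w_s·Δt
```

with `R` i.i.d. mean-0 variance-`r` noise (uniform on `[−√(3r), √(3r)]`
by default; a Gaussian option exists — both satisfy the scheme's moment
requirements) so the displacement standard deviation is
`sqrt(2·K·Δt)` evaluated at the offset depth. The surface is reflective
(`z' ← −z'`); there is no bottom boundary because the study site drops to
more than 500 m, but an optional reflective floor supports the standard
well-mixed validity check (an initially uniform ensemble must stay
uniform between two reflective boundaries). That check is run across 20
seeds with a Kolmogorov–Smirnov test at α = 0.01 and allowed at most 2
rejections: under a correct scheme rejections are false positives with
expectation 0.2 of 20, while omitting the drift correction rejects in
all 20, so the 2-of-20 allowance separates the two cleanly without being
flaky.

Parameter defaults: initial depths `N(26.4, 3)` m truncated at the
surface (the observed release depth band; gametes are released at
20–30 m), 10 000 particles, `r = 1`. `K0 = 10⁻³ m² s⁻¹`, `z_MLD = 20 m`
and `w_s = 0` are placeholder upper-ocean scales — site-specific mixing
measurements should replace them for scientific use, and the simulation
logs a notice when they are used as-is.

The particle cloud is reduced to `C(z,t)` by a two-dimensional Gaussian
kernel density estimate computed as a binned KDE (2-D histogram on the
output grid followed by Gaussian smoothing), which is numerically
equivalent at grid resolution and fast enough to sit inside replicated
experiments. Boundary bias at the surface is removed by reflecting the
data about z = 0 before binning (`f(z) + f(−z)`). Bandwidths default to
Silverman's rule per axis and are overridable. Each time slice is
renormalized to trapezoidal integral 1; slices are bilinearly
interpolated at observation points, and evaluation outside the gridded
span is an error rather than an extrapolation.

## Horizontal kernel

The point-release solution with mortality. Diffusivities are kept in
m² h⁻¹ internally (the natural reporting unit at survey scale);
`convert_diffusivity_units` handles m² s⁻¹. The kernel is singular at the
release instant, so evaluation requires `t > t0`. Mass balance
(`∬C dx dy = e^{−μ(t−t0)}`) is verified by quadrature in the tests.

## Likelihood and fitting

The imaging system counts eggs per minute while sampling 264 l min⁻¹.
The negative binomial is defined on integers, so the likelihood is
evaluated on the raw counts with the sampled volume as exposure: the
expected count in minute *i* is `e^β·C(x_i,y_i,z_i,t_i)·v_i/1000` with
`v_i` in litres and `C` in (relative) m⁻³ — statistically equivalent to
fitting the derived concentrations `Y_i = count/264` but coherent for a
count law. Variance is `m + m²/k`; the Poisson limit `k → ∞` is an
oracle test.

Optimization is L-BFGS-B on `(β, log Kx, log Ky, log μ, log k)` with five
jittered starts (seeded; identical data and seed reproduce the AIC
exactly), box bounds wide enough to be inert in practice, and a
moment-matched starting β. Non-convergence is flagged on the results
object, never raised. Degenerate means are clipped at 10⁻³⁰⁰ and
non-finite likelihoods replaced by a large penalty so the optimizer can
retreat.

Profile 95% intervals are the values where the re-optimized negative
log-likelihood rises `χ²₁(0.95)/2 = 1.9207` above the minimum, found by
doubling bracket expansion plus Brent root refinement on the log scale;
an endpoint that reaches the box bound is returned at the bound
(one-sided interval). On a quadratic log-likelihood this reproduces
±1.96·SE to the root tolerance.

The nested-submodel lattice is: full `{Kx, Ky, μ}`, isotropic `{K, μ}`,
no-mortality `{Kx, Ky}`, isotropic no-mortality `{K}` and intercept-only,
each with β and k always free; AIC compares them.

**Deviance explained.** Both the model and the intercept-only null
deviance are evaluated at the *model's* dispersion estimate `k̂` (the
NB-GLM convention): deviances computed under two different dispersions
are not commensurable and can rank a clearly better-fitting model below
the null. The null mean is the ML constant concentration with the volume
exposure. With this convention the statistic is 0 for the null, 1 for a
saturated fit, and increases with signal-to-noise on synthetic data.

## Egg production and prediction

Total annual production is mature abundance × female ratio (default 1:1)
× mean fecundity over the length distribution; the 95% CI scales the
total by the relative abundance CI (fecundity uncertainty is not
modelled). The built-in fecundity-at-length is an explicit placeholder
power law (`a·L^b`, a = 2, b = 3, L in cm); real analyses must supply the
species' estimated relation, including its length convention. Production
is split 40/40/10/10 across two peak and two minor spawning nights;
allocation conserves the total exactly (fractional eggs are retained).

Prediction maps are vertically integrated (per m²): the plume centre is
the interpolated drifter position, spread comes from the fitted
anisotropic kernel, and decay uses two-stage mortality — the fitted egg
rate to hatching at 24 h, then 0.576 day⁻¹ (converted to h⁻¹ internally)
for yolk-sac larvae, the mean of published warm-water estimates. The
default grid half-width is 3σ of the wider axis (≥ 99% of the surviving
mass); narrower grids warn with the captured fraction.

## Synthetic surveys

The generator emulates the study conditions: a 15 h survey starting 0.5 h
after release (the boat moves in as spawning ends), a drifter following a
correlated-velocity (Ornstein–Uhlenbeck) walk with 0.15 m s⁻¹ RMS speed
and 3 h persistence, a tow alternating 1 and 2 km transects perpendicular
and parallel to the drifter heading at 1.5 m s⁻¹ relative speed,
triangle-wave undulation between 1 and 30 m at 3 cycles km⁻¹ (sinusoidal
depth profiles differ negligibly for sampling purposes), and per-minute
NB counts at 264 l min⁻¹. True rates default to `Kx = 14 900`,
`Ky = 49 100 m² h⁻¹`, `μ = 0.172 h⁻¹`. The overdispersion default
`k = 0.5` reflects the strong clumping typical of plankton counts; β is
calibrated so the peak expected count along the tow is ~20 min⁻¹,
matching the order of a real night's yield (~2·10³ eggs over a survey).
NB draws use the exact Gamma–Poisson mixture; everything is bit
reproducible under a fixed seed.

What the generator does **not** emulate: vertical current shear,
shelf-interaction events (drifters grounding, the abrupt lateral
spreading seen when a plume hits shallow topography), scale-dependent
(non-Fickian) diffusion, tides and wind-driven surface drift decoupling,
net avoidance or imaging misclassification. Passing recovery tests
therefore demonstrate estimator correctness under the model's own
assumptions — not robustness to these field complications.

## Recovery experiment and problem sizes

The headline self-check simulates 20 replicate surveys (one shared
vertical field of 10 000 particles, since the vertical physics is common
and assumed known by the separable model; fresh drifter, tow and counts
per replicate; ~870 observations each), refits the full model, and
profiles `Kx` and `μ`. Median estimates land within a few percent of the
generating values and the 95% profile intervals cover them at close to
nominal rate. These sizes keep the complete experiment around ten
seconds on one core while leaving Monte-Carlo error well below the
effects being checked.

## Known limitations

* The exposure formulation assumes counts within a minute are exchangeable;
  splitting minutes changes the likelihood value slightly (sums of NB are
  not NB), though estimates are stable.
* `C(z,t)` is treated as known when fitting; vertical-field Monte-Carlo
  error is not propagated into the horizontal-parameter intervals.
* Mortality and diffusivity are confounded with β at very short
  observation spans; identifiability here rests on the 0.5–15 h leverage.
* Equirectangular projection limits the frame to ~1° around the origin
  (ample for plume scales; verified against a haversine oracle).
* The intercept-only deviance null, the closed diameter window
  `[0.87, 1.20] mm`, and the five-submodel lattice are package choices
  where the underlying conventions are genuinely open.
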