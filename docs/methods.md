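# Methods

## Model and assumptions

The core is a steady-state, linearised leaf energy balance.  Net
isothermal radiation is partitioned into sensible heat, thermal
re-radiation and latent heat; linearising the saturation vapour-pressure
curve about air temperature gives the closed-form two-term quotient for
the leaf-to-air temperature difference ΔT_e (radiative warming minus
evaporative cooling).  The model assumes:

- no leaf heat storage (instantaneous equilibrium with the microclimate);
- sky temperature equal to air temperature, sky emissivity 0.97, leaf
  emissivity 0.97 by default — with equal emissivities the isothermal
  longwave term vanishes and `R_ni` reduces to absorbed shortwave;
- the linearisation `e_sat(T_leaf) ≈ e_sat(T_air) + s·ΔT`, accurate to a
  few percent for |ΔT| below ~5 °C (the energy-closure test verifies the
  reconstructed sensible + latent flux balances `R_ni`);
- a forced-convection boundary layer, `g_b,H = a·(U/W)^b`, identical over
  the whole leaf.

### Closures

Several quantities admit more than one standard formulation; the ones
used here are deliberately simple and are all configurable constants so
alternatives can be swapped in:

- `g_b,W = 1.08·g_b,H` (heat→water diffusivity-ratio correction);
- `r_b,HR = 1/(g_b,H + g_b,R)` — heat and radiative paths in parallel;
- `g_b,R = 4·ε·σ·T³/(ρ_a·c_pa)`, the linearised radiative conductance;
- `γ = c_pa·P/(0.622·λ_v)`; `ρ_a` from the ideal-gas law at the site
  pressure (default 90 kPa, ~1,000 m elevation) unless a constant
  override is supplied;
- shortwave: `R_sw = α_sw·(PAR/q)/f_PAR` with absorptance α_sw = 0.50,
  quantum conversion q = 4.57 µmol J⁻¹ and PAR fraction f_PAR = 0.50.
- The `g_b,H` relation is treated as the whole-leaf (projected-area)
  conductance with no extra two-sidedness factor: the calibration step
  refits the coefficient directly against inverted field resistances, so
  geometric factors are absorbed into `a`.

### Inversion

Holding the `r_bHR ↔ r_bW` coupling (both derive from the same `g_b,H`),
the energy balance is exactly quadratic in `r_bW`, so the inversion is
closed-form rather than iterative.  The inverse map is two-valued over
part of the state space: an observation can sit on either side of the
resistance at which the temperature response peaks.  When wind speed and
leaf width are available, the root nearer (in log ratio) the
forced-convection prior resistance is returned; otherwise the larger
(boundary-layer-limited) root, which is the physical branch throughout
the low-wind, within-canopy regime.  Ambiguous records are flagged
`multi_root`, unsolvable ones `no_root`, and zero-forcing records
(`R_ni = 0`, `D = 0`, where any resistance satisfies the balance)
`degenerate`; downstream calibration uses only `ok`/`multi_root` records.

### Boundary-layer calibration

The flat-plate coefficient `a = 0.0105` (exponent 0.5) overpredicts
resistance at the low wind speeds typical inside canopies.  Calibration
inverts observed ΔT records with PAR ≥ 200 µmol m⁻² s⁻¹ for `r_bW`, then
fits `r_bW = 1/(1.08·a·(U/W)^b)` by nonlinear least squares on the
resistance scale (a flag switches to conductance scale), either with `b`
fixed at 0.5 (one-parameter) or free (two-parameter).  The fit uses raw
points; the 0.1 m s⁻¹ wind-binned means ± SD with per-bin Tukey fences
(1.5 × IQR) are used for display, and the same fence rule is exposed as a
mask for pre-screening raw points where PAR mismatch contaminates the
inversions.  Initial values are the defaults (a₀ = 0.0105, b₀ = 0.5);
asymptotic standard errors come from the Jacobian.

### Stomatal response and thermal time constant

Spot conductance is modelled as `g_s ~ 0 + species + species:D` with a
leaf random intercept (single shared variance), fitted by REML through
statsmodels MixedLM: the intercept is leaf-specific, the slope
species-specific.  Fits with an unidentifiable random effect (fewer than
two leaves in a species, or an estimated random-intercept variance at
zero) fall back to per-species OLS and are flagged.  Predictions are
floored at g_min = 5 mmol m⁻² s⁻¹ because the fitted lines extrapolate
below zero at large D, which is unphysical and would place an infinite
resistance in the energy balance.

The thermal time constant is computed as

    τ = φ·LMA·[c_pw/LDMC + (c_pd − c_pw)] / H,
    H = ρ_a·c_pa·(g_b,H + g_b,R + g_s·s/γ),

with φ = 0.5 (projected/total area for flat leaves), LMA converted
g m⁻² → kg m⁻² internally, c_pw = 4,181 and c_pd = 2,814 J kg⁻¹ K⁻¹.
The bracketed grouping — water mass per dry mass (1/LDMC) at the heat
capacity of water, plus dry matter at its own heat capacity — is the
dimensionally consistent reading of this standard formulation; the
alternative grouping (dividing the whole bracket by LDMC·H jointly) is
not dimensionally coherent and is not used.

### Window selection and contrasts

Daytime records (top-of-canopy PAR > 5 µmol m⁻² s⁻¹; the threshold is a
package choice) are split into 20-minute windows aligned to clock
boundaries.  Within each (leaf, window) group the predicted ΔT_e is
regressed on the observed ΔT — in that direction, so the gate reads "the
prediction tracks the measurement" — and the window is kept when the
slope lies in 1 ± 0.3, the intercept in ± 2 °C, and at least n_min = 60
of the 120 possible 10-s points are present.  Selection is idempotent.
Species contrasts on the selected, microclimate-binned data use
`ΔT ~ species` with a leaf random intercept; marginal and conditional
pseudo-R² follow the variance-partition definition
(fixed / [fixed + random + residual], and fixed + random over the same
denominator).  Microclimate bins are half-open `[lo, hi)` on PAR, air
temperature and wind and are fully user-configurable.  An optional
balanced subsample caps the number of records per 250-µmol PAR bin below
1,000 µmol m⁻² s⁻¹ to offset the skewed sampling of bright conditions.

## Synthetic scenario

The generator emulates a 10-day spring campaign on an instrumented
montane-forest tower at 10-s cadence and five sensor heights
(2–25 m):

- **Sky** — clear-day sinusoidal PAR peaking at 2,000 µmol m⁻² s⁻¹,
  a per-day brightness factor (uniform 0.35–1, mixing overcast and sunny
  days) and multiplicative 10-minute cloud flicker (probability 0.3,
  depth up to 0.6); Beer-law vertical attenuation through a leaf-area
  index of 4 with extinction coefficient 0.5.  Night PAR is exactly 0.
- **Air temperature** — nocturnal base 12.4 °C with a bright-day
  amplitude of 10 °C at the canopy top, damped with depth; these values
  put the daytime top-of-canopy mean near 15 °C and sunny-day maxima
  near 22 °C.
- **Humidity** — linear in air temperature (intercept 1.25, slope
  −0.03 K⁻¹, noise SD 0.03, clipped to [0.3, 1]), giving the tight
  negative coupling the gap-fill regression assumes (R² ≈ 0.8).  A
  scenario flag masks the leading fraction of days to emulate a
  late-starting sensor.
- **Wind** — lognormal (shape 0.5) with mean 0.26 m s⁻¹ within the
  canopy rising to 1.0 m s⁻¹ at the top.
- **Leaves** — three species: a shallow-responding overstorey species
  (g_s = 325.1 − 68.8·D, boundary coefficient 0.0171, width 6 cm,
  10 leaves at 8–18 m), a high-intercept steep-slope overstorey species
  (401.6 − 189.8·D, 0.0215, 12 cm, 9 leaves at 8–14 m) and a
  low-conductance understorey species (185.4 − 212.7·D, width 3.5 cm,
  4 leaves at 1.5–4 m, default boundary coefficient).  Leaf intercept
  offsets are Normal(0, 30 mmol m⁻² s⁻¹); spot residuals
  Normal(0, 40).
- **Leaf temperature streams** — the forward model under each leaf's
  true traits and g_s(D) line, plus thermocouple noise
  (SD 0.05 °C, appropriate to a calibrated differential thermocouple).
  In a configurable fraction (default 0.2) of daytime 20-minute windows
  the PAR driving the truth is rescaled by a factor from {0.3, 2.0}
  while the recorded PAR is unchanged, emulating tower/leaf-surface
  mismatch; these windows are what the selection statistic must reject.

Every generator is a pure function of (scenario, seed) with independent
sub-streams for the roster, sky, profiles, spots and corruption, so the
same scenario is byte-identical across calls.

What the generator does *not* emulate: wet-leaf episodes after rain or
fog (which push real leaves below air temperature), radiative night-time
decoupling beyond what the energy balance produces, sensor drift, leaf
angle effects on intercepted PAR, and autocorrelated gusts.  Passing
tests therefore demonstrate the correctness and statistical calibration
of the *pipeline* under its own assumptions, not the field realism of
those assumptions.

## Numerical choices

- Wind is floored at 0.05 m s⁻¹ inside the conductance law only, to keep
  resistances bounded; the calibration module, not the floor, addresses
  the physical overprediction at low wind.
- D is exposed in kPa everywhere but enters the energy balance in Pa;
  the conversion is internal and tested.
- Predicted humidity is clipped to [0.01, 1] so D stays defined under
  extrapolation; wind profiles clamp (never extrapolate) outside the
  sensor span so speeds stay non-negative.
- Humidity gap-fill is fitted per sensor height (the coupling strength
  varies with depth); leaves take the model of the nearest sensor
  height.  Heights with under 10 paired points or zero temperature
  variance are refused.
- The quadratic inversion is exact algebra; no root-finder tolerances
  are involved.  NLS uses analytic-free curve_fit with at most 2,000
  function evaluations and errors out with diagnostics rather than
  returning an unconverged fit.
- Skewness is the adjusted Fisher–Pearson sample statistic and is
  reported missing for constant series.
- Multi-logger streams are merged on exact timestamps; the CSV reader
  pivots long records and leaves gaps as NaN rather than resampling.

## Problem sizes

The shipped scenario (10 days × 5 heights × 10-s cadence, 23 leaves) is
the package's reference configuration: the full pipeline completes in
under a minute on one CPU, and the test suite uses two-day or
one-minute-cadence reductions of the same scenario where the full volume
adds nothing to the property under test.  Calibration recoveries use
2,000-point wind sweeps; statistical-calibration checks use 100–200
replicates.

## Known limitations

- The leaf random intercept uses a single shared variance across
  species; strongly heteroscedastic leaf effects would call for
  per-species variances (not implemented).
- Mixed-model p-values are Wald-based; with very few leaves per species
  they are only approximately calibrated (the type-I test pins this at
  the shipped design, 6 leaves × 20 observations per species).
- The two-parameter boundary-layer form fixes the functional family
  `a·(U/W)^b`; free-convection behaviour at U ≈ 0 is out of scope.
- Counterfactual trait swaps change model parameters only; they do not
  relocate the leaf, so microclimate exposure (height, D regime) stays
  with the base leaf by design.
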