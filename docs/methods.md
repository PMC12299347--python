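# Methods

## Scope and units

The package treats chloride as a conservative tracer of soil-water
movement in the sampled 0–45 cm profile of ridge-tilled potato fields.
Concentrations are water-soluble Cl⁻ in mg per kg dry soil; stocks are
kg Cl per hectare; rainfall is cumulative mm since basal fertilization.
Fractions are used internally everywhere; percentages appear only in
printed output and serialized reports.

## Stock accounting

`ClA = C·BD·D·0.1` converts a layer concentration to an area stock; the
0.1 is the exact dimensional factor for (mg/kg)·(g/cm³)·cm → kg/ha
(1 ha × 1 cm of soil at 1 g/cm³ weighs 10⁵ kg). Budgets are taken against
the unfertilized control at the same sampling date, so background Cl⁻ and
any common-mode change (atmospheric input, background leaching) cancel:

    ClLF = (Cl_r − (ClA_T − ClA_CK)) / Cl_r,   ClRR = 1 − ClLF − ClP.

The grouping of ClLF is chosen so that treated = control reads as 100%
leached. Measurement noise can push ClLF outside [0, 1]; values are kept
unclamped and flagged (clamping would silently bias budgets toward
closure). The plant uptake fraction ClP is an input parameter (default
0.05, a few percent of the dose, consistent with harvest-stage residual
rates a few points below the profile residual); it is not estimated from
the data.

Profile stocks sum the three 15-cm layer stocks after averaging replicate
concentrations per layer.

## The residual estimation model

`Y = 38.518 − 0.219·X₁ + 0.143·X₂ + 0.557·X₃` predicts profile-aggregate
residual Cl⁻ (mg/kg) from rainfall (mm), Cl dose (kg/ha) and clay (%).
Design choices:

* **Clamping, not raising.** Large rainfall at low dose drives the affine
  prediction negative; this is read as "fully leached" and clamped to 0
  with a flag. Inversions and round-trip identities operate on the
  unclamped branch.
* **Extrapolation flags, not hard bounds.** The calibration envelope is
  narrow (clay 9.8–12.9%); predictions outside it are flagged rather than
  refused.
* X₁ is raw cumulative rainfall; canopy interception is not subtracted
  (interception is one reason field leaching runs behind bare-soil
  simulation, and the model's rainfall slope already embodies it).

Both planning inversions are closed-form solutions of the affine model;
negative solutions are truncated to 0 with a status flag ("already below
target" / "target unreachable at zero dose"). Refitting is ordinary least
squares (statsmodels) with per-coefficient standard errors; a rank check
precedes the fit and names constant or pairwise-collinear columns.

## Validation metrics and rubric

R² is computed as 1 − SSE/SST about the measured mean (it can be
negative and equals the squared correlation only for the least-squares
line); NRMSE normalizes RMSE by the observed range (max − min), not the
mean; PBIAS follows Σ(measured − modeled)/Σmeasured × 100, so positive
PBIAS means under-prediction. The rubric bands are |r| > 0.8, R² > 0.75,
NRMSE < 0.5 and |PBIAS| ≤ 25% for "very high", with printed band edges
assigned to the better class (band endpoints overlap in the customary
rubric tables). A constant measured series makes NRMSE undefined and is
rejected; n ≥ 3 pairs are required.

## Leaching analysis

Per-layer rainfall responses are least-squares quadratics
`conc = a·rain² + b·rain + c`; the reported correlation column is the
*linear* Pearson r of rain vs content (negative for declining layers even
when the parabola opens upward), matching how such tables are
conventionally printed.

Critical rainfall for a target leaching efficiency inverts a straight
line fitted to the efficiency series. Efficiency is concave in rain, so a
line fitted over a whole season overshoots near the origin and distorts
low targets; `fit_max_efficiency` restricts the fit to points at or below
a chosen efficiency (a local linearization, still a least-squares line).
The calibration checks use a 0.6 ceiling for the 30% target and the
global line for the 80% target. Solutions beyond 1.25× the observed rain
range are flagged as extrapolation; a non-positive slope is an error, not
a number.

## Yield safety

Relative yield (% of control, replicates and years averaged per dose
before fitting) is fitted as a quadratic in dose; the safe window is
solved on the descending limb only (roots above the vertex), matching the
rise-then-fall shape of potassium response followed by chloride toxicity.
Curvature below 1e-12 in magnitude is treated as non-concave (constant
yields fit to |p2| ≈ 1e-18). Toxicity classes follow the agronomic bands
(95–100% safe, 80–90% mild, <50% severe); the gaps [90, 95) and [50, 80)
are filled with `marginal` and `moderate` labels that carry a `gap_fill`
flag because they interpolate beyond the published rubric. The vertex of
a shallow quadratic is ill-conditioned; recovery tests therefore use the
package's default curve (pronounced optimum) and medians over replicates.

## Synthetic-trial generator

The generator reproduces the *conditions* of a two-site, two-year
rain-fed trial: loam (BD 1.32, clay 12.9%) and sandy loam (BD 1.36, clay
9.8%) sites with pre-season backgrounds of 8.6–12.5 mg/kg per layer;
doses 0/37.5/75/112.5 kg Cl/ha; three replicates; ~130-day seasons
totalling 340 mm (dry preset) or 700 mm (wet preset); Gaussian
measurement noise of 1 mg/kg by default.

**Rainfall** is a daily wet/dry process with a light/heavy event mixture
(light ≈ Exp(2.2 mm); heavy ≈ 8 mm + Gamma(2, 5.5), i.e. ≈ 19 mm events)
and a higher heavy-event probability in the first 40 days; the series is
scaled to the configured seasonal total, so re-seeding changes timing
while changing the total only rescales amounts.

**Exogenous Cl⁻** travels as a Gaussian pulse in depth: after effective
rain `x` the centre is at `z = 2 + 0.38·x` cm and the spread is
`σ = 3 + 0.0563·x^1.207` cm; mass below 45 cm counts as leached, mass the
kernel puts above the surface is folded into the top layer. Texture
enters through an effective-rain warp — sandy loam behaves as if it had
received extra rain, an advantage shaped as a hump peaking near 60 mm
(bare-soil infiltration contrast) and vanishing later (canopy and
wet-season fluxes equalize the textures) — and higher doses leach
slightly faster (+6% effective rain per dose step above the medium dose,
reflecting saturable adsorption). Layer concentration is background plus
the layer's share of the dose divided by the layer soil mass; the control
is background only. SO₄²⁻ is carried as an inert, slowly declining
covariate with no effect on Cl⁻.

The pulse constants were calibrated once, jointly, to the trial's stated
milestones and then frozen: ≈85% of exogenous Cl⁻ still in 0–15 cm at
20 mm of rain; the 15–30 cm layer holding the largest share (~45%) at
70 mm; treated–control convergence (profile-mean difference < 5 mg/kg) at
270 mm; end-of-season (300 mm) profile residual ≈ 11% of the dose, i.e. a
residual ratio of ≈6% after 5% plant uptake; and loam requiring ≈1.5×
the sandy-loam rainfall at 30% leaching efficiency but ≈1.0× at 80%.
An earlier design that used the published per-layer quadratics directly
as the generating truth was abandoned: their season-wide fit intercepts
are extrapolation artifacts at low rain (they would put only ~38% of the
exogenous Cl in 0–15 cm at 20 mm) and several 30–45 cm rows do not
converge per-layer by 270 mm. The published quadratics remain in
`reference.py` as recovery targets for the curve-fitting code and as the
documentary record of the layer responses.

What the generator does *not* emulate: within-field spatial correlation,
preferential-flow heterogeneity, heteroscedastic or non-Gaussian assay
error, rainfall-intensity effects beyond the light/heavy mixture, and any
SO₄²⁻–Cl⁻ interaction. Tests passing on synthetic trials therefore
demonstrate that the estimators recover a known truth under the stated
noise — not that the truth model is correct for any particular field.

## Validation simulation (headline numbers)

`simulate_model_validation` builds a 10 × 3 × 2 grid (rainfall 20–300 mm,
the three doses, the two clay contents), takes the model's raw
predictions as truth, and adds Gaussian noise with sd equal to 5.5% of
the predicted-value range — the error scale of a well-validated field
model (range-normalized errors of 0.05–0.06). Medians over 100 replicates
give R² ≈ 0.96 and NRMSE ≈ 0.05, inside the headline bounds R² ≥ 0.9 and
NRMSE ≤ 0.1. Raw (unclamped) predictions are used on both sides so the
exercise measures the metric machinery, not the clamping rule.

## Problem sizes and determinism

Default analysis runs use 9 sampling dates × 4 treatments × 3 layers × 3
replicates (324 observations) per trial; Monte-Carlo checks use 5–100
replicates. These sizes give stable medians while keeping any run in
seconds. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` children (rainfall/profile/yield streams are
independent), so every table is bit-identical under a fixed seed.

## Known limitations

* ClP is a constant fraction, not a growth-stage-dependent uptake model.
* The residual model is validated, not re-derived; its provenance
  (simulation experiments on texture series) is outside this package.
* The safe-window bounds depend on the fitted quadratic's tails; with
  only four dose levels the 95% bound inherits substantial uncertainty
  that the point estimate does not show.
* Layer geometry is fixed at three 15-cm layers; deeper profiles require
  re-deriving the leached-mass convention.
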