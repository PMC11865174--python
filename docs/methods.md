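# Methods

`pvecophys` re-implements, as a tested pipeline, the derivation-and-inference
chain of a two-species browsing-legacy field study: raw leaf dehydration,
fluorescence/gas-exchange, vessel-anatomy and biomass measurements are turned
into ecophysiological traits, and those traits into treatment × species ×
date contrasts and a trait ordination.  Because the underlying field data are
not public, a calibrated synthetic-cohort generator stands in for them; this
note records the models, the calibration conventions, and what the generator
does and does not emulate.

## Pressure–volume analysis

A dehydration sequence is a series of (fresh mass, Ψ) pairs recorded while a
rehydrated leaf dries on the bench, plus an oven dry mass.  The water
potential decomposes as Ψ = P + π with turgor pressure P ≥ 0 and osmotic
potential π < 0.  With relative symplastic content
R = (RWC − R_a)/(1 − R_a), where R_a is the apoplastic water fraction, the
model underlying both the forward generator and the extraction is

- dilution law: π = π₁₀₀ / R,
- linear elastic turgor: P = max(0, −π₁₀₀ + ε·(R − 1)).

Turgor vanishes at R_tlp = 1 + π₁₀₀/ε, so beyond the turgor-loss point
−1/Ψ is linear in RWC.  The extraction pipeline:

1. **Saturated mass.**  OLS of fresh mass on Ψ over the 4 wettest points,
   extrapolated to Ψ = 0.  The intercept is used only if the slope is
   positive and the intercept is at least the largest observed mass
   (oversaturation guard); otherwise the maximum observed mass is used and a
   warning logged.  On model-generated curves the intercept over-estimates
   the true saturated mass by < 0.2 % (the mass–Ψ relation is mildly
   concave), which propagates to < 0.5 % error in the other parameters.
2. **Linear region.**  The fit of −1/Ψ on RWC starts from the 5 driest
   points and grows one wetter point at a time while the enlarged fit keeps
   R² ≥ 0.995 *and* the candidate's residual stays below 2× the region's
   residual SD (with a tiny absolute floor so exactly collinear points are
   never rejected by a zero SD).  The R² threshold gates extension only; the
   initial 5-point fit is always accepted, because at realistic bench noise
   (Ψ ± 0.02 MPa) even a perfectly post-TLP quintet has R² ≈ 0.95.
3. **Parameters.**  π₁₀₀ = −1/(a + b) (line at RWC = 1); R_a = −a/b; the
   turgor-loss point is the wettest member of the region, with π₀ the
   line's value there — with the line in hand this is a noise-robust
   substitute for intersecting a noisy concave curve with its own tail, and
   it makes the identity π₀ = π₁₀₀ (1 − R_a)/(rwc_tlp − R_a) hold exactly.
   D_W/T_W = dry mass / saturated mass.
4. **Bulk modulus.**  Pre-TLP turgor is P = Ψ − π(RWC) with π taken from the
   fitted line.  ε_max is the magnitude of the least-squares slope of P
   against R over the 4 wettest pre-TLP points.  A max-pairwise-slope
   variant (`eps_method="max_pairwise"`) is provided, but it is not the
   default: pairwise slopes divide noisy ΔP by small noisy ΔR and taking the
   maximum biases the estimate upward without bound (≈ +65 % median error at
   bench noise, vs ≈ 11 % for the OLS slope; both are exact on noise-free
   curves, where turgor declines linearly and any slope estimator returns ε).

All thresholds (wet window k = 4, R² 0.995, residual gate 2 SD, ε window 4)
are keyword arguments with these defaults.

Recovery, measured by the test suite: on noise-free forward-model curves all
six parameters return within 1 % (worst ≈ 0.5 % over 100 random parameter
sets); at bench noise (mass ± 1 mg, Ψ ± 0.02 MPa) median errors are ≈ 2 %
for π₁₀₀ and ≈ 11 % for ε_max.

## Gas exchange, hydraulics, allometry

Standard derivations, kept deliberately thin:

- Φ_PSII = (Fm′ − Fs)/Fm′; ETR = Φ_PSII · PPFD · 0.5 · 0.84 (equal
  excitation partitioning between photosystems, C3 leaf absorbance 0.84);
  iWUE = A_area/g_s; LMA = dry mass/area (g m⁻²);
  A_mass = 1000·A_area/LMA (nmol g⁻¹ s⁻¹).  The identity
  A_mass·LMA = 1000·A_area holds for every derived record.
- k_sth = (πρ/128η)·ΣD⁴/S with D the equivalent circular vessel diameters
  (µm → m) and S the sapwood sector area (mm² → m²).  Water constants
  default to 20 °C (ρ = 998.2 kg m⁻³, η = 1.002×10⁻⁹ MPa s) and are exposed
  as arguments; the source study states neither a temperature nor values.
  Lumen areas are accepted and converted via D = √(4A/π).
- LA = total leaf dry mass × (subsample area / subsample mass);
  S_A/L_A = basal cross-section / LA (also reported ×10⁴ to match the
  display convention); R/S = root/shoot dry mass.  The sapwood proxy line
  sapwood = 0.94·cross-section − 0.061 (cm²) is a fixed calibration used
  descriptively, never re-fitted in the derivation path; the test suite
  re-estimates it from synthetic stems as a pipeline check.

## Synthetic cohort

The generator emulates the study design: 2 species (a deciduous beech-like
FAGUS and an evergreen holly-like ILEX) × 2 browsing histories × 5 plants,
measured on six campaigns (late spring / midsummer / late summer × 2 years),
with pressure–volume curves once per year in late summer, vessel sets for
three growth rings (roots excavated for FAGUS only), and a single final
harvest.

**Calibration.**  Trait calibrations are stored as species and treatment
*marginal* means taken from the published group statistics, folded into cell
means additively (the printed marginals of LMA, A_mass, g_s and [N] are
mutually consistent to three digits, so both marginals are recovered
exactly) or multiplicatively for S_A/L_A, SB and LA, whose printed groups
are unbalanced or species-scaled.  Dispersions are reconstructed as
sd = SE·√n with the basis n recorded per trait (5 plants for harvest
traits, 10 curves for pressure–volume traits, 30 plant×date records for
repeated traits); within-cell variance is split evenly between a
plant-level intercept and a record-level residual, which is exactly the
structure the downstream mixed models assume.

**Identities, not independent draws.**  Raw observables are generated from
latent traits through the same identities the derivation modules invert:
leaf dry mass = LMA·area·10⁻⁴, A_area = A_mass·LMA/1000, Fm′ = Fs/(1 − Φ),
dry mass = (D_W/T_W)·saturated mass, root mass = (R/S)·shoot mass, basal
cross-section = (S_A/L_A)·LA.  A noise-free cohort therefore round-trips
exactly, and a noisy one up to the configured instrument noise (0.5 %
relative on masses/areas, 1 mg and 0.02 MPa on the PV bench).  Because R/S
and S_A/L_A are free latents, the *derived* per-plant ratios match their
printed means; the implied organ means (e.g. root biomass) then deviate a
few percent from their printed counterparts — the printed mean-of-ratios
and ratio-of-means are themselves inconsistent, and the ratios are what the
study's contrasts (and this package's checks) grade.

**Water potential.**  A latent base follows a chosen seasonal predawn
trajectory (−0.35 → −0.85 MPa; the study prints no absolute predawn means);
midday Ψ subtracts a positive species drawdown sized so the species means
hit the printed −1.04/−1.72 MPa.  The browsing legacy enters as a +0.25 MPa
predawn offset confined to late-summer of the drier first year (midpoint of
the reported 0.2–0.3 MPa), attenuated (+0.10 MPa) for the evergreen in the
second year; it is added after the midday value is formed, so midday stays
browsing-free, as observed.  Predawn ≥ midday holds record by record by
construction.

**Date effects** are zero-sum seasonal profiles (≈ ±10 % amplitude,
drought-shaped) — qualitative only, since no per-date table is printed;
cell means averaged over dates are unchanged.  **Distributions** are
Gaussian, truncated or clipped only where a physical bound is within reach
(fractions, signs); shoot biomass and leaf area are lognormal with matched
mean and sd, since sapling sizes are strongly right-skewed (printed SB
dispersion implies cv > 1).  Vessel diameters are lognormal with species ×
organ location parameters chosen so the deciduous species out-conducts the
evergreen in every ring year, as reported.

**What the generator does not emulate:** spatial structure, browsing
events, climate drivers (dates are categorical), instrument drift,
within-crown trait gradients, correlated trait noise beyond the defining
identities, or missing data.  Passing calibration-recovery tests therefore
shows the derivation-and-inference chain is correct and unbiased under the
study's published first and second moments — not that it is robust to every
pathology of real field data.

## Statistical stage

- **Outlier screen.**  Type-7 quartiles; extreme = outside Q1 − 3·IQR /
  Q3 + 3·IQR; removed = extreme and beyond 10× the crossed fence's
  magnitude.  Fences are placed within species × treatment cells: the
  species contrast spans up to an order of magnitude for several traits, so
  pooled fences would measure the design, not anomalies.  Both multipliers
  are arguments.
- **Mixed models.**  REML linear mixed models (statsmodels) with a plant
  random intercept; treatment, species, date and all interactions as fixed
  effects; backward elimination drops the least significant currently
  droppable term (marginality respected) with P ≥ 0.05 until none remains.
  P values are marginal Wald F tests with sum-to-zero contrasts and
  nlme-style containment denominator df (between-plant terms tested in the
  plant stratum, date-involving terms in the within stratum), which
  reproduces split-plot F tests on balanced data; the measured null
  rejection rate of the treatment term is 0.055 at 200 replicates.  A
  log₁₀ transform is applied automatically when the full model's residuals
  fail a Shapiro normality check or show a variance–mean trend; all-negative
  responses (water and osmotic potentials) are transformed on magnitudes
  with the sign restored and flagged.  Singular mixed fits fall back to an
  ordinary linear model with a diagnostics flag.
- **Tukey HSD** over dates runs only when the date effect is retained as
  significant, on the model's response scale, with a compact letter display
  built from the maximal cliques of the not-significantly-different graph.
- **Once-measured traits** (S_A/L_A, stem anatomy: treatment × species;
  root-linked and harvest traits: treatment only, on the excavated species'
  subset) use the same selection loop on OLS models; single-factor models
  refuse tables containing more than one species.
- **PCA** on the 10 treatment-responsive traits (g_s, A_mass, LMA, [N],
  π₁₀₀, π₀, D_W/T_W, ε_max, S_A/L_A, SB), repeated traits entering as
  per-plant means across dates (one point per plant; a per-date entry mode
  would multiply points, not plants, and is not what the ordination plots).
  Traits are z-scored; components are sign-fixed so each component's
  largest-magnitude loading is positive; rank deficiency (e.g. duplicated
  columns) is detected and reported.  On the study-scale cohort the first
  two components explain 73–82 % of variance across seeds, the first
  separating the species, the second the browsing histories.

## Problem sizes and numerical checks

Mean-recovery checks run at 500 plants per cell (≈ 12 000 records, 4 000
dehydration curves; ≈ 15 s), where configured means are recovered within
2 %.  The selection-loop type-I check uses 4 plants per cell × 3 dates ×
200 null replicates.  Degenerate inputs are defined errors: curves with
fewer than 8 points, fewer than 5 dry points, non-positive apoplastic
slope, ε ≤ |π₁₀₀| in the forward model (turgor-loss point at or below the
apoplastic limit), empty vessel sets, non-positive sapwood areas,
single-level factors, constant traits in the PCA.

## Known limitations

- Containment df are exact only for balanced designs; heavily unbalanced
  data would need Satterthwaite/Kenward–Roger approximations, which the
  fitting backend does not provide.
- The ε_max convention (window size, slope estimator) is a documented
  choice; published values from other protocols can differ by the window.
- The Tukey stage compares date means pooled over the other factors, as in
  the source analysis; it does not condition on retained interactions.
- The sapwood proxy line is treated as exact calibration; its uncertainty
  is not propagated.
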