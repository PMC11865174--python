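# pvecophys

Plant-ecophysiology trait pipeline for browsing-legacy studies: from raw
leaf dehydration sequences, gas-exchange/fluorescence records, xylem vessel
anatomy and biomass harvests to derived water-relations, hydraulic and
allometric traits — and on to mixed-model treatment contrasts and trait
ordination.  A calibrated synthetic-cohort generator emulates the full
2 species × 2 browsing-history × 5 plants × 6 campaign field design, so the
whole derivation-and-inference chain is reproducible and testable without
access to the (undeposited) field data.

Intended users: plant ecophysiologists analysing pressure–volume curves and
leaf economics traits, and anyone needing a transparent, tested reference
for the standard derivation chain.

## What it computes

**Pressure–volume parameters** (per dehydrating leaf).  Beyond the turgor
loss point, −1/Ψ is linear in relative water content; the fitted line gives
the osmotic potential at full turgor π₁₀₀ = −1/(a + b), the apoplastic
fraction R_a = −a/b, the turgor-loss point (RWC_tlp, π₀) and, from the
pre-TLP turgor P = Ψ − π(RWC), the maximum bulk modulus of elasticity
ε_max = |dP/dR_s| near full turgor.  D_W/T_W is the dry-to-saturated mass
ratio.

**Gas exchange.**  Φ_PSII = (Fm′ − Fs)/Fm′,
ETR = Φ_PSII · PPFD · 0.5 · 0.84, iWUE = A/g_s, LMA = m/A_leaf, and
A_mass = 1000·A_area/LMA.

**Hydraulics.**  Theoretical sapwood-specific conductance from vessel
lumina via Hagen–Poiseuille: k_sth = (πρ/128η)·Σ Dᵢ⁴ / S.

**Allometry.**  Total leaf area from a subsample, root-to-shoot ratio,
and the Huber-value proxy S_A/L_A.

**Statistics.**  3×IQR extreme-outlier screening, REML mixed models
(treatment × species × date, plant random intercept) simplified by backward
elimination with split-plot-style F tests, Tukey HSD across dates with
compact letters, and a PCA on the 10 treatment-responsive traits.

## Worked example

Run the whole chain — simulate a cohort from the packaged field
calibration, derive every trait, screen, model, ordinate:

```bash
pvecophys all --seed 42 --out out/
```

prints (abridged):

```
psi_pd       retained: D, T:D
g_s          retained: D, S
lma          retained: S, T, T:S
a_mass       retained: D, S, T, S:D
n_conc       retained: D, S, T
pi_100       retained: T
eps_max      retained: T
sa_la        retained: S, T
root_shoot   retained: T
sksth_2018   retained: S, T
PCA: PC1 45.5% + PC2 28.2% = 73.7% of variance
```

Reading: at the study's own sample size the browsing treatment (T) is
retained for leaf construction cost (LMA), mass-based photosynthesis
(A_mass), leaf nitrogen, the osmotic parameters (π₁₀₀) and wall elasticity
(ε_max), biomass partitioning (R/S) and hydraulic architecture (S_A/L_A);
species (S) dominates the leaf-economics traits; and the first two
principal components capture 73.7 % of trait variance, the first separating
the two species, the second the browsing histories.  Model P values,
elimination paths, Tukey letters and PCA loadings/scores are written to
`out/`.

Library use mirrors the CLI:

```python
from pvecophys import generate_pv_sequence, PVCurveRaw, extract_parameters

seq = generate_pv_sequence(pi_100=-1.5, eps=10.0, r_a=0.3,
                           dry_mass=0.4, turgid_mass=1.0, n_points=14, seed=0)
curve = PVCurveRaw(seq["fresh_mass_g"].to_numpy(), seq["psi_MPa"].to_numpy(),
                   dry_mass=0.4)
p = extract_parameters(curve)
print(round(p.pi_100, 3), round(p.pi_0, 3), round(p.rwc_tlp, 3),
      round(p.r_a, 3), round(p.eps_max, 2), round(p.dw_tw, 3))
# -1.5 -1.765 0.895 0.3 10.0 0.4
```

The extracted parameters equal the generating ones: π₀ and RWC at turgor
loss follow the closed forms R_tlp = 1 + π₁₀₀/ε and π₀ = π₁₀₀/R_tlp.

## Layout

- `src/pvecophys/config.py` — cohort configuration, packaged calibration,
  YAML round trip
- `src/pvecophys/synthetic_cohort.py` — cohort, dehydration-sequence and
  vessel-set generators
- `src/pvecophys/pv_analysis.py` — pressure–volume parameter extraction
- `src/pvecophys/gas_exchange.py`, `hydraulics.py`, `allometry.py` — trait
  derivations
- `src/pvecophys/stats_pipeline.py` — outlier screen, model selection,
  Tukey HSD, PCA
- `src/pvecophys/pipeline.py`, `cli.py` — end-to-end chain and CLI
- `docs/methods.md` — model assumptions, calibration conventions, numerical
  choices and limitations
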