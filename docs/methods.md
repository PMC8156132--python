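# Methods

This note documents the models, conventions and numerical choices behind
`proreq`, and what its synthetic data do and do not establish.

## The requirement model

The factorial estimate of net protein requirements treats nitrogen
intake as a linear function of growth on metabolic-weight-scaled axes:

    y_i = b0 + b1 * x_i + e_i,
    x_i = ADG_i (g/kg W^0.75/d),   y_i = N intake_i (g N/kg W^0.75/d)

fitted by ordinary least squares (statsmodels OLS). The intercept b0 is
the N intake at zero gain — the net maintenance requirement per kg of
metabolic weight — and the slope b1 is the marginal N cost per gram of
gain (the W^0.75 scaling cancels in the slope, leaving g N/g ADG).
Crude-protein equivalents multiply by the Kjeldahl factor 6.25 g CP/g N.

Assumptions: linearity of intake in gain across the observed range
(negative gains included — the lowest-CP group loses weight and anchors
the left of the line), homoscedastic errors, and one independent point
per animal. Trial records carry two 45-day periods per animal; the
default collapses them to the animal mean before fitting so the sample
size equals the number of animals (a `per_period` option exists but
doubles apparent n and pseudo-replicates).

Display convention: the N-scale estimates are rounded half-up to 3
decimals *before* the ×6.25 conversion (0.0725 → 0.073 → 0.46 g CP/g
ADG), matching how such requirements are conventionally quoted; the
unrounded conversions are available as `maintenance_cp` / `growth_cp`
properties. Uncertainty comes from the OLS standard errors and, as a
distribution-free alternative, a case-resampling bootstrap (percentile
intervals; resamples with zero ADG spread are redrawn since the slope is
then undefined).

## Nitrogen balance and intake accounting

All balance quantities follow from three measured flows by exact
identities: excretion = fecal + urinary N; absorption = intake − fecal;
retention = intake − excretion. Retention and digestibility may be
legitimately negative on noisy data and are flagged, never clipped.
N intake is derived from CP intake / 6.25 (diet CP is itself N × 6.25,
so this reconstructs the diet's N content exactly).

Ratios are computed per animal and then averaged (mean of ratios), not
from group means: treatment-table statistics such as gain:feed are only
reproducible this way. Metabolic scaling uses W^0.75 of the mean of the
period's initial and final body weight.

Apparent digestibility is 100·(intake − fecal)/intake. The record
schema carries fecal DM and fecal N only, so DM and CP digestibility
come directly from the records; OM/NDF/ADF digestibilities additionally
need a user-supplied fecal-composition map (g/kg fecal DM), since fecal
nutrient assays are not part of the core schema.

## The purine-derivative chain

Urinary purine derivatives (PD: allantoin, uric acid, xanthine,
hypoxanthine, mmol/d) index the duodenal flow of microbial purines.
The chain is:

1. total PD = component sum (always the computed sum, never a
   transcribed total);
2. absorbed purines PB invert the linear excretion model
   PD = slope·PB + endo·W^0.75. The coefficients are species
   conventions and therefore configuration, not constants: the default
   is the swamp-buffalo convention (slope 0.12, endogenous 0.20
   mmol/kg W^0.75 — buffaloes recover far less absorbed purine in urine
   than cattle); `RunConfig.cattle_purine_convention()` gives the cattle
   pair (0.85, 0.385). PD at or below the endogenous floor maps to
   PB = 0;
3. microbial N (g/d) = PB · 70/(0.116 × 0.83 × 1000) = 0.727·PB, from
   purine N content 70 mg/mmol, purine-N:total-N 11.6:100 in mixed
   rumen microbes, and purine digestibility 0.83;
4. creatinine-normalised indices: A:C, PD:C and the PDC index
   (PD/creatinine)·BW^0.75, robust to incomplete urine collection
   because creatinine excretion is proportional to muscle mass;
5. microbial-N efficiencies per intake denominator. DOMR (digestible OM
   apparently fermented in the rumen) is a configurable fraction
   (default 0.65) of digestible OM intake, with digestible OM intake
   approximated through DM digestibility; the CP-intake efficiency is
   expressed per gram of CP intake, which is the magnitude convention
   in published tables of this statistic.

## RCBD statistics

The experimental model is Y_ij = µ + B_i + T_j + ε_ij with animals'
weight groups as blocks; the ANCOVA variant adds a centred covariate
β(X_ij − x̄) (only centring makes the adjusted means invariant to the
covariate's origin). Sums of squares are the sequential decomposition
computed by nested least-squares fits; on a balanced complete design
this is the unique orthogonal decomposition, and an explicit
projection-matrix oracle in the test suite verifies agreement to 1e-10.
Numerically-zero sums of squares (constant response) are snapped to
zero at a relative 1e-12 threshold and F statistics are then reported
as undefined rather than 0/0.

Polynomial trend tests build orthonormal contrast coefficients by QR
factorisation of the Vandermonde matrix of the *actual* CP levels
(5.4, 6.6, 8.5, 10.5) — not integer scores; for equally spaced levels
the coefficients reduce to the classical (−3,−1,1,3)/(1,−1,−1,1) tables
up to scale. Contrast SS = n·(c·means)²/(c·c), F against the error mean
square with 1 df.

Duncan's multiple range test sorts means descending and declares a
consecutive stretch homogeneous when its extremes differ by less than
R_p = q(span p, error df) · √(MSE/n), with the studentized-range
quantile taken at Duncan's protection level 1 − (1−α)^(p−1). Quantiles
are computed numerically from `scipy.stats.studentized_range` (cached —
the distribution function is expensive) rather than hard-coded tables,
so any error df is supported. Letters are assigned to maximal
homogeneous stretches in rank order. Fisher's LSD threshold is reported
alongside as the pairwise yardstick.

## The synthetic generator

`generate_trial` emulates the study conditions: 16 animals, 4 CP levels
× 4 blocks, 2 periods of 45 d, initial BW ~233 kg. Per-treatment
generating means are the published group means of the trial's summary
tables, per-animal SD = SEM·√4, Gaussian noise throughout (tables
report one pooled SEM, so no heteroscedasticity by default). An
additive N(0, 5 kg) block effect acts on initial weight (blocks were
weight groups). A shared per-animal appetite factor (correlation 0.6)
ties DM intake to gain within treatment. Offered feed is intake/0.90,
so refusals are ~10% of offer. Hard accounting identities are enforced
by construction (refusals ≤ offer, fecal DM < intake, N excretion ≤ N
intake); `allow_inconsistent=True` skips the clamps and inflates N
outputs so validator tests receive dirty data. Fixed config + seed is
byte-reproducible.

What the generator does **not** reproduce: the individual-animal
scatter of the original regression. The published group means imply a
group-level N-intake~ADG line (intercept ≈ 0.64, slope ≈ 0.11) that
differs from the published individual-level fit (0.8663, 0.0725,
R² = 0.577) — group means and the n = 16 regression are not mutually
consistent, and a moment-matching generator necessarily follows the
former. Trial-level fits on generated data therefore run at R² ≈ 0.78
with intercepts near 0.7. For parameter-recovery experiments the
package instead uses `generate_requirement_points`, which draws points
directly from the requirement model: x cycles through the four
group-level ADG/W^0.75 values (−0.84, 2.62, 4.65, 7.97) with
within-group jitter SD 1.6 g/kg W^0.75/d (the per-animal ADG SD implied
by the published SEM at the mean metabolic weight), and the noise SD is
set in closed form, σ² = b1²·Var(x)·(1−R²)/R², so the *population* R²
equals the target. Sample R² at n = 16 is slightly upward-biased
(≈ +0.02–0.03 at these settings), an intrinsic property of R̂², not a
calibration error.

Passing tests on synthetic data show the pipeline's arithmetic,
statistics and estimator implementations are correct under the assumed
Gaussian moment structure; they cannot validate the physiological
realism of any particular trial.

## Problem sizes and tolerances

The recovery experiment uses 200 replicates of 16 points (seconds on
one CPU); oracle-equivalence checks use 100 random balanced designs at
1e-10; the null calibration of the linear contrast uses 2000 replicates
with a 3-binomial-SE acceptance band around α = 0.05. Composition and
balance identities are asserted to machine precision or to the printed
precision of the reference values they reproduce.

## Known limitations

* Apparent (not true) digestibility; no passage-rate or compartmental
  digestion modelling.
* The spot urinary-PD model only; no plasma PD kinetics or isotope
  methods.
* Single-covariate ANCOVA; no repeated-measures or mixed-model REML
  machinery (periods are averaged per animal).
* TDN components are user inputs, not estimated from proximate
  analysis; diet ME is always the computed TDN conversion (the
  uniformly rounded value sometimes printed in diet tables is not
  stored).
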