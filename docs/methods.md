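# Methods

## The model

Daily time use is a 4-part composition `x = (sleep, st, lpa, mvpa)` on
the 1440-min simplex; canonical part order is fixed as above throughout
the package. Analyses use pivot isometric log-ratio (ILR) coordinates.
For pivot part `p` with the remaining parts `(r1, r2, r3)` kept in
canonical order,

    z1 = sqrt(3/4) · ln( x_p / g(r1, r2, r3) )
    z2 = sqrt(2/3) · ln( r1 / g(r2, r3) )
    z3 = sqrt(1/2) · ln( r2 / r3 )

with `g` the geometric mean. The contrast matrix `V` (columns = the
log-contrast weights of `z1..z3`) is orthonormal with zero column sums,
so the coordinates are invariant to closure scaling and the four pivot
systems are rotations of one another: any model linear in `z` gives
identical likelihood, variance components and predictions under every
pivot. Only the interpretation of `z1` changes, which is why the
rotation table refits the model four times and reads off `β1` each
time. The first-pivot coefficient relates to the centred log-ratio
(clr) coefficient vector `a` (which sums to zero) by
`a_p = sqrt(3/4) · β1_p`; consequently the four `β1` values from exact
fits of the same data sum to zero, and a printed, 2-dp-rounded
quadruple sums to zero within 0.02.

The outcome model for score `y` of child `i` in school `s` is

    y_is = β0 + β·z(x_is) + γ'·c_is + u_s + e_is,
    u_s ~ N(0, τ²),  e_is ~ N(0, σ²)

with covariates `c` = (age, sex [girl = 0], BMI z-score, IMD decile,
all entered linearly). REML estimates are reported for coefficients,
standard errors (Wald z p-values) and variance components. The omnibus
question — is the composition associated with the outcome at all? — is
answered by a likelihood-ratio test comparing ML fits with and without
the three-coordinate block, referred to χ²(3). REML likelihoods are
not comparable across fixed-effect sets, hence the ML refits; the
(small) REML/ML discrepancy in σ̂ also means effect sizes quoted from a
REML fit differ negligibly from ML ones — the package uses the
residual SD of whichever fit produced the substitution model, REML by
default, and uses the level-1 σ̂ only (not the total SD including τ²),
reading "residual standard deviation" literally. Stratified analyses
(by sex, school type, or both) drop the stratifier from the covariate
set; school-type strata also drop age, whose variation is almost
entirely between school types.

## Isotemporal substitution

For base composition `x0` and the composition `x1` obtained by moving
`t` minutes from one behaviour into another (other parts untouched, sum
preserved), the predicted difference is the log-contrast
`Δ(t) = Σ_j a_j (ln x1_j − ln x0_j)`; intercept, covariates and school
effects cancel. Δ is continuous and monotone in `t` when the two clr
coefficients involved have opposite signs, and is asymmetric in the
direction of exchange whenever the two parts differ in size at the
base — the behavioural reason reallocations *out of* a small MVPA
budget predict larger losses than equal reallocations into it predict
gains. The substitution grid spans −20…+20 min in 5-min steps by
default; grid points that would drive a part to zero or below are
flagged infeasible and carry NaN deltas rather than being clamped or
dropped, so plotted curves cannot silently distort. The default base
composition is the cohort's (or stratum's) compositional mean — the
part-wise geometric mean closed to 1440 min — with an override
available. Effect size is `Δ / σ̂`.

The pipeline gate mirrors the analysis it implements: rotation tables,
the dominant behaviour (smallest first-coordinate p among those
< α, ties broken by larger |β1|) and substitution grids are produced
only for outcome × stratum cells whose omnibus test is significant.
Multiple outcomes are tested without multiplicity correction by
default, matching the analysis the package reproduces; a Bonferroni
switch (`bonferroni=True`) divides α by the number of outcomes.

## Synthetic cohorts

The generator draws what the model assumes, so every downstream stage
is testable without data access:

- **Compositions** are logistic-normal: `z ~ N(z*, Σ)` in sleep-pivot
  ILR space, with `z*` the ILR image of the target compositional mean
  (defaults: sleep 543.2, ST 635.8, LPA 210.1, MVPA 50.9 min — the
  published cohort's centre). Because the ILR mean equals `z*`, the
  population compositional mean is exactly the target. The default
  `Σ = diag(0.15², 0.15², 0.35²)` is an order-of-magnitude choice — the
  within-cohort log-ratio spread is not recoverable from published
  summaries — giving roughly ±10% day-to-day spread on the
  sleep-vs-rest contrast and a wide (±40%) spread on the LPA/MVPA
  contrast, the most variable behaviour pair; it is config-exposed.
- **Schools**: 12 (10 primary, 2 secondary), membership
  multinomial-uniform; school effects drawn once per school per
  outcome. This is the simplest exchangeable structure consistent with
  a single random intercept; it does not reproduce the published
  cohort's imbalanced school sizes (≈210 primary vs 149 secondary
  pupils).
- **Covariates**: age Normal(10.4, 0.7) in primary and Normal(13.0,
  0.3) in secondary schools; sex Bernoulli(0.493 boys); BMI z-score
  Normal(0.39, 1.21); IMD decile a rounded Normal(7.3, 2.3) clipped to
  1–10 — all matching published descriptives marginally, not jointly.
- **Outcomes**: `y = intercept + a·ln x + covariate effects + school
  effect + noise`, continuous and unbounded. Truncating to the scoring
  ranges (0–54 overall, 0–18 subscales) would bias the recovery
  experiments that are the generator's purpose, so it is deliberately
  omitted. The paper-like configuration uses the published first-pivot
  coefficients (clr-converted, re-centred to exact zero sum) for the
  overall, process and time scores, a null composition effect for the
  product score (whose omnibus test was not significant), residual SDs
  (6.5, 2.9, 3.3, 1.9) and school SDs (2.0, 0.9, 1.0, 0.6) sized so
  total score SDs land near the published descriptives, intercepts
  centring each score at its published mean, and modest covariate
  effects (e.g. boys +2.5 overall points, +0.3 points/year of age)
  chosen to be realistic in sign and size; they are generator choices,
  not published estimates.

What passing tests therefore show: the pipeline recovers its own
generative truth (each clr effect's ±2·SE interval covers truth in
90–99% of 200 replicates), the omnibus test is calibrated (type-I error
within [0.03, 0.07] at α = 0.05 over 1000 null cohorts of n = 360), and
the deterministic arithmetic reproduces the published reallocation
value from the published inputs. What they do not show: robustness to
features the generator omits — measurement error in accelerometer
classification, missingness/imputation, bounded and discrete scores,
non-normal school effects, or joint covariate structure.

## Numerical choices

- Closure total 1440 min, hard-coded as the default and exposed as an
  argument; every emitted composition sums to it within 1e-9 relative.
- Zero handling: multiplicative replacement with a 1-min floor before
  closure (raised parts set to the floor, others shrunk
  proportionally), preserving log-ratio validity for plausible MVPA
  zeros. Replacement is infeasible when 4 × floor ≥ the input total.
- Mixed-model optimisation: statsmodels defaults, with a
  Powell→Nelder-Mead fallback chain for the boundary case τ̂² = 0,
  where the default optimizer's Hessian is singular; the fallback
  reproduces the boundary (OLS) likelihood to ~1e-8.
- A fitted between-school variance below 1e-4 × the residual variance
  is reported as a boundary fit: `random_intercept_sd = 0`,
  `singular = True`, plus a warning. The LRT statistic is floored at 0.
- Constant ILR columns (a composition identical across participants)
  are excluded from the omnibus full model, yielding χ² = 0 rather
  than a singular design; any other rank deficiency raises an error
  naming the collinear columns.
- Seeded runs are byte-identical: simulated cohorts round compositions
  to 1e-9 min and outcomes to 1e-6 score points before writing, and
  replicate seeds are spawned from a `SeedSequence` (kept below 2³¹).

## Problem sizes

Simulation-based checks run at the conditions they emulate — n = 360,
12 schools — with 200 replicates for coverage and 1000 for test
calibration; the full default suite completes in a few minutes on one
core. Smaller fixtures (n = 36–80, 2–4 schools) back the exact-identity
and brute-force-likelihood tests, where the property checked is
scale-free.

## Known limitations

- Four fixed parts only; no amalgamations, sub-compositions, robust or
  Bayesian CoDA variants.
- Single random intercept; no random slopes, crossed effects or
  small-sample df corrections (p-values are Wald z; the omnibus LRT
  relies on the asymptotic χ² reference).
- The bundled reference coefficients are printed to 2 dp, which bounds
  agreement of the worked example to ±0.01–0.05 in the reallocation
  deltas.
- Real cohort CSVs must be complete; imputation is upstream of this
  package (rows can be rejected or complete-case filtered only).
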