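# Methods

## Outcome definitions

Four binary cardiovascular conditions are derived per participant as
composite OR-rules over measurements and self-reports:

| condition | rule |
|---|---|
| hypertension | SBP ≥ 140 mmHg, or DBP ≥ 90 mmHg, or self-reported history, or antihypertensive medication |
| IHD | self-reported heart attack / angina / chest pain (pass-through) |
| stroke | self-reported history (pass-through) |
| dyslipidaemia | lipid-lowering drugs, or diagnosis, or TC ≥ 6.22, TG ≥ 1.69, LDL ≥ 4.14 mmol/L, or HDL < 1.04 (men) / < 1.29 (women) |

Diabetes (a covariate) is HbA1c ≥ 6.5 %, history, or treatment; BMI classes
are underweight < 18.5 ≤ normal < 25.0 ≤ overweight. All "≥" cut-offs are
inclusive and HDL/BMI-underweight are strict "<", exactly as printed in the
standard definitions; BMI "normal" is the half-open interval [18.5, 25.0).

Missingness is handled by the unique monotone completion of an OR-rule: any
positive evidence yields 1 even with other fields missing; 0 requires at
least one observed field and no positive evidence; otherwise the outcome is
missing. Records are never imputed. A record whose only HDL evidence is
blocked by a missing sex is flagged in the derivation report rather than
silently resolved.

## Survey estimation

Prevalences are Hájek ratio estimates p̂ = Σwᵢyᵢ/Σwᵢ. Confidence intervals
are logit-scale Wald with a Taylor-linearised ratio variance and an n/(n−1)
finite-sample factor; this keeps intervals inside [0,1] and attains
93–97 % empirical coverage at n = 500, p = 0.3 (checked by simulation). At
p̂ ∈ {0,1} the logit degenerates, so a one-sided Clopper–Pearson-style
bound on the effective sample size (Kish n_eff = (Σw)²/Σw²) is substituted
and flagged. Missing outcomes are dropped pairwise with their weights.
PSU/stratum clustering is not modelled; the variance is documented as
linearised complete-case. Two weight columns (interview and biomarker, the
latter inflated by the inverse consent rate) let the differential-weighting
workflow be exercised; the estimators consume whichever column they are
given.

## The poverty index

SAMPI = H × A per district, where H is the share of households whose
weighted deprivation share reaches the poverty cutoff k, and A is the mean
weighted deprivation share among those poor. Defaults: k = 1/3 (the global
MPI convention the index is based on) and nested equal weights over four
dimensions (education, health, living standards, economic activity — the
source alternately mentions five dimensions in one passage; we implement
the four of the definitional list). Both are configurable. District
quintiles use ascending 1-based ranks with stable ties and
quintile = ⌈5r/n⌉, which for n = 52 gives partition sizes
(10, 10, 11, 10, 11).

## The joint spatial model

See the README for the likelihood and prior structure. Numerical and
design choices:

* **Sampler.** Pólya–Gamma augmentation: ω_ik ~ PG(1, η_ik) per observed
  cell, then per-condition Gaussian block updates of (α_k, β_k),
  single-site systematic-sweep updates of each district row S_j
  (conditional prior N(neighbour mean, Σ_s/m_j)) and V_j (prior
  N(0, Σ_v)), recentering, and conjugate Wishart draws for both
  precisions. The PG(1, z) draws use Devroye's exact alternating-series
  rejection sampler (numba-compiled; validated against closed-form moments
  and an independent truncated infinite-sum construction). An adaptive
  random-walk Metropolis sweep over the same full conditionals exists
  purely as a cross-check and agrees with the Gibbs sampler on small
  instances.
* **Identification.** After each sweep every column of S is recentred to
  sum to zero with the mean folded into α_k, leaving the linear predictor
  unchanged (asserted to 1e-12 in tests). Islands (districts with no
  neighbours) have no ICAR conditional; their structured effect is pinned
  at 0 and a warning is emitted when the graph is built — a standard
  GeoBUGS-compatible convention, and a package choice since real
  non-contiguous districts could be handled differently. Recentring
  averages over non-island districts only, so islands stay exactly 0.
* **Wishart updates.** df* = prior_df + rank(Q) = prior_df + (J −
  n_components) for Σ_s⁻¹ (the intrinsic prior is rank-deficient by one
  per connected component) and prior_df + J for Σ_v⁻¹;
  scale* = (scale₀⁻¹ + S'QS)⁻¹ resp. (scale₀⁻¹ + V'V)⁻¹. The prior scale
  matrix is the identity with df = K by default (the source does not print
  its scale matrix); both are configurable.
* **Flat intercept prior** is implemented by omitting the intercept's
  precision term; propriety comes from the data plus the sum-to-zero
  constraint.
* **Missing outcome cells** contribute no likelihood term and no PG draw
  (complete-cell analysis).
* **Survey weights are not used in the fitting likelihood** — the model is
  an unweighted Bernoulli likelihood; weights belong to the descriptive
  survey estimates only.
* **Defaults.** 2 chains (differing by seed only), 10,000 iterations,
  5,000 burn-in, thin 5; convergence flag at split-R̂ < 1.1 on all
  monitored fixed effects. Chains are seeded as `default_rng([seed,
  chain])`, so a run is bit-reproducible from its manifest.
* **Degenerate inputs.** Non-SPD Wishart scales, non-finite states and
  failed Gaussian solves raise immediately with iteration context rather
  than continuing.

Odds-ratio tables summarise exp(β) by posterior median and equal-tailed
2.5/97.5 percentiles with reference levels printed as 1.00; spatial odds
exp(S_jk + V_jk) are summarised the same way plus the exceedance
probability P(exp(U) > 1).

Smoking is emulated with three levels (never / ex-smoker / current); a
two-level coding (never / ever) is available through the design-matrix
`recode` option since published tables use both conventions.

## The synthetic generator

The generator is the exact dual of the fitted model: same linear
predictor, same S + V decomposition. The intrinsic CAR draw is spectral —
eigendecompose Q, drop null eigenvectors, give the coefficients of
eigenvector e with eigenvalue λ covariance Σ_s/λ — which is the only exact
sampler on the identified subspace of the improper prior.

Study conditions (defaults): J = 52 districts; per-district sample sizes
lognormal with median 277 and mean 346 truncated to [22, 1625] (the
distribution family is a package choice; only those three statistics are
given by the emulated survey); K = 4 conditions with marginal prevalence
targets 0.286 (hypertension), 0.054 (IHD), 0.018 (stroke), 0.531
(dyslipidaemia) — intercepts are calibrated numerically per dataset so the
population-average probability hits the target given the drawn covariates
and effects; covariate category frequencies follow the emulated survey's
weighted totals; Σ_s and Σ_v are exchangeable-correlation matrices
(sd 0.35/0.20, ρ = 0.4) giving positive cross-condition spatial
correlation; district SAMPI scores are drawn in [0.008, 0.1] (the observed
extremes of the real index), iid by default or spatially autocorrelated on
request.

Raw clinical fields are back-filled from the generated binary outcomes:
one sufficient positive field (chosen at random among measurement and
self-report routes for biomarker consenters, self-report only otherwise)
per positive outcome, all-negative observed fields otherwise. This is a
round-trip device that makes `derive_outcomes` reproduce the generated
outcomes exactly; it is not a physiologic simulator — lipid panels, blood
pressures and HbA1c have no realistic joint distribution, self-report
validity statistics computed on synthetic data are artifacts of the
back-fill routes, and covariates are drawn independently rather than with
realistic cross-tabulations. Passing tests therefore demonstrate
correctness of the estimators and sampler under the model, not robustness
to real-data misspecification.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the default suite
fast while preserving their statistical meaning: the parameter-recovery
study uses 5 replicates of J = 52, K = 2, n ≈ 15,000 with 2 chains × 1,500
iterations (the analysis driver `analysis/07_recovery_study.py` scales the
same study up arbitrarily); the spatial-spike recovery uses 20 single-chain
fits at J = 20, n = 3,000; conjugacy checks use 10⁵ Wishart draws and a
24,001-point quadrature grid. The recovery bands (posterior-median OR for
a true OR-2 effect inside (1.6, 2.5); credible-interval coverage in
[0.85, 1.0]; split-R̂ < 1.1) are fixed properties of the study design, not
tuned quantities.

## Known limitations

* Areal adjacency only (binary queen/rook contiguity); no
  distance-weighted or covariate-weighted neighbourhoods.
* No shared-component or spatio-temporal variants; no model selection
  (DIC/WAIC).
* Design-based variance ignores PSU/stratum clustering.
* The GeoJSON contiguity reader snaps coordinates at 1e-8° and calls any
  shared boundary point a neighbour; heavily slivered digitisations may
  need pre-cleaning.
* Single-site S updates mix adequately here because district likelihoods
  are informative; very sparse districts with strong spatial correlation
  would benefit from block updates, which are not implemented.
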