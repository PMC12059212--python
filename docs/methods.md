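# Methods

## The system being modelled

A fully occupied colony of nest boxes (default 246 boxes on ~80 ha) is
monitored with RFID readers that log every PIT-tagged bird entering a box.
Breeding pairs own boxes; surplus males ("floaters") visit active nests
throughout the season. The pipeline quantifies (i) when floaters visit,
(ii) where each floater concentrates its visits, and (iii) whether the next
year's settlement is predicted by proximity to the prospected area, by the
previous occupants' success and phenotype, or by the previous owner's
disappearance.

## Detection processing

Raw reads pass four steps, in order:

1. **Bout filter.** A (box, day) enters the analysis only if at least
   120 min of reader coverage were recorded; multiple bouts on one day pool
   their hours.
2. **Read deduplication.** Within each (tag, box) stream a read is dropped
   if it falls less than 8 s after the last *retained* read. Anchoring to
   the retained read makes the filter idempotent (a second pass changes
   nothing).
3. **Stage classification.** With lay date L, clutch size c, hatch date H:
   pre-laying is [L−14, L), laying [L, L+c) (one egg/day), incubation
   [L+c, H), and nestling bins by age a = date − H: 1–7, 8–14, 15–18, and
   19–22 d. Intervals are closed on the left, open on the right; the hatch
   day itself (a = 0) is excluded, as is anything past day 22.
4. **Status scoring.** A bird breeding in the first clutch wave is a breeder
   all season; one breeding only in a later wave is a transitioning floater
   until its lay date and a breeder after; a bird never recorded breeding is
   a floater throughout. Both floater classes are pooled in all counts.
   The male owner of a brood is the most frequent male visitor during chick
   rearing whose feeding visits reach ≥20% of the female's; ties are flagged
   unresolved rather than broken arbitrarily.

The per box-day response is the number of *distinct* male floater tags
detected (owners excluded), with log recorded-hours as offset. Broods enter
the stage models only when both parents are tagged and at least 8 nestling-
period days were recorded.

## Mixed-model engine

Four families are fitted by maximum marginal likelihood:

* Poisson and Bernoulli GLMMs with log/logit links, an offset entering the
  linear predictor with coefficient 1, and one or two random intercepts.
* The zero-truncated Poisson, pmf p(y|λ) = λ^y e^{−λ}/(y!(1−e^{−λ})) for
  y ≥ 1, used as the count part of a hurdle model whose zero part is a
  Bernoulli GLMM for P(zero). The parts have orthogonal likelihoods and are
  maximized separately; the offset enters the count part only.
* Gaussian LMMs by REML (statsmodels MixedLM), used only to residualize
  covariates; crossed random effects are expressed as variance components
  inside a single enclosing group. When the fixed effects fit the response
  (near-)perfectly the REML problem is degenerate and the exact OLS solution
  is returned instead.

**Integration.** One grouping factor: adaptive Gauss–Hermite quadrature.
Per group the conditional mode of b ↦ ℓ_g(b) − b²/2σ² is found by a
vectorized damped Newton iteration; 15 nodes (default) are centred and
scaled by the mode and curvature. Two crossed factors: a joint Laplace
approximation, maximizing the penalized log-likelihood over the full
random-effect vector by Newton steps on the (q₁+q₂)-dimensional Hessian
(block structure: two diagonals plus the cross-classification count
matrix), with log L = f(û) − ½ log det H − Σⱼ qⱼ log σⱼ.

**Optimization.** Bounded quasi-Newton (L-BFGS-B) on (β, log σ) from two
starts — the GLM fit with σ ∈ {0.1, 1.0} — followed by a short Nelder–Mead
polish. The finite-difference step is set explicitly to 1e-6 because the
inner solvers leave noise below that scale which otherwise stalls the line
search. log σ is bounded in [−7, 3]; estimates at or below log σ = −5 are
flagged as boundary fits. A grouping factor with a single observed level is
pinned at σ² = 0 (the variance is unidentifiable) and flagged; with no
groups the fit reduces exactly to the GLM (deviance agreement ~1e-6 against
statsmodels).

**Inference.** Fixed-effect covariance comes from the inverse numerical
Hessian of the negative marginal log-likelihood at the optimum (central
differences). Type-III Wald tests use χ² = β'V⁻¹β over each term's
coefficient block; odds ratios are exp(β) with Wald 95% CIs. On shared
fixtures the engine matches `lme4::glmer` (nAGQ = 15 and Laplace) to ~1e-4
in β, SE and σ². Note lme4's reported logLik for nAGQ > 1 drops constants
and is not comparable; ours is the absolute marginal log-likelihood.

The nestling-age polynomial in the hurdle model is a raw quadratic on the
standardized age (mean 0, sd 1). Published coefficient tables for such
models depend on the (unstated) basis, so coefficient *scales* are not
comparable across bases — the sign pattern and the Wald tests are.

## Home ranges and the settlement test

The MCP-95 of a floater-year takes the distinct visited-box coordinates
(a box visited many times counts once; at least 5 distinct boxes required),
removes the points whose distance to the arithmetic-mean centre exceeds the
95th percentile (linear interpolation between order statistics; ties at the
cutoff retained), and returns the convex hull and its area. The colony-wide
*median* MCP area defines a circle radius r = √(A/π) projected on every
polygon centroid; boxes within r (boundary inclusive) form the floater's
candidate set. An alternative nearest-rank percentile and the
mean-of-points centroid are switchable but off by default.

Two permutation statistics compare settlement with a colony-random null in
which every floater's settlement box is re-drawn uniformly (with
replacement across floaters, own box not excluded): the mean
centroid-to-nest distance (lower tail) and the count of floaters settling
inside their own circle (upper tail), with the add-one estimator
p = (1 + #extreme)/(B + 1). The tests are exact-valid for any B; null
calibration across 200 replicates puts the type-I error at α = 0.05 within
±0.03.

## Settlement-choice models

For each floater the candidate set is the boxes in its circle plus the box
actually chosen (kept even if outside the circle). Predictors come from the
candidate box's *latest* previous-year attempt (second wave if present):
total young fledged that year, second-brood young fledged, second-brood
failure (boxes with no second attempt are coded 0 fledged / failed — this
keeps the reproductive-success models at full sample size, matching how
analyses of this design report identical n across those predictors), owner
age (minimum age when only a first-capture year is known), ornament length
(mean of three throat-feather measurements), body condition, brood-size-
corrected provisioning rate, and owner disappearance (tag absent from all
detections and breeding records of the settlement year). Each predictor is
fitted univariately — missingness shrinks each model's n independently — as
a binomial GLMM with floater identity and year as crossed intercepts.
Complete separation (runaway coefficient) is flagged and the estimate
withheld.

Body size is PC1 of the beak/wing/tarsus correlation matrix (sign chosen so
loadings are non-negative); body condition is the conditional residual of
mass ~ PC1 + capture time + capture date with year and individual as
crossed random effects; the provisioning correction is the residual of
rate ~ brood size with a year intercept.

## Autocorrelation

Temporal: for lag k, all within-box pairs (x_t, x_{t+k}) of annual fledged
counts are pooled across boxes and correlated (pooling is more stable than
averaging per-box ACFs over short series). Manipulated box-years are
excluded upstream. Spatial: Moran's I with binary weights per 100-m
distance class (row-standardized mode available), permutation p two-sided
around the null expectation −1/(n−1), 999 value permutations.

## Synthetic colony generator

The generator emulates the study conditions: 246 boxes uniform on an 80-ha
square; every box breeds every year (first wave; a random ~30% add a second
wave); modal clutch 4 (truncated Poisson ≥1); incubation 12 d; fledging by
day 22–23; male owner survival 0.57 per year (the observed range is
0.54–0.60), survivors philopatric, casualties replaced by recruits.
Fledged counts follow a per-box latent AR(1) quality process whose
stationary lag-1 correlation (default 0.25) plants the temporal
autocorrelation; rounding to counts attenuates the realized Pearson
correlation by sd²/(sd²+1/12) ≈ 4%, inside the recovery tolerance. Quality
innovations carry a small spatially smooth component (default: 20% of the
variance from an exponential-correlogram field with 100 m range), which
leaves the across-year mean fledged count weakly positively autocorrelated
at the most proximal distance lag only — the pattern expected of a
saturated colony with near-identical boxes — while keeping the per-box
marginal process unchanged. Floater
counts per year default to 60 (no field abundance estimate exists; 60 gives
a floater:breeder ratio plausible for a saturated colony). Each floater
draws 5 + Poisson(10) distinct boxes (clipped to the observed 5–46 range,
mean ~15) without replacement with probability ∝ exp(−d²/2sd²) around a
personal centre; in the degenerate sd → 0 limit this reduces to the m
nearest boxes. Detections per (floater, visited box, bout) are
Poisson(0.05 reads/h × hours × stage multiplier), with nestling-week
multipliers (3, 6, 7, 6) against 1 elsewhere; the low base rate keeps
distinct-floater counts unsaturated so the stage contrast survives
counting. Settlement the following year is an independent multinomial logit
over all boxes with log-odds −d(box, centroid)/distance_decay +
vacancy_logOR·1[owner died] — independence across floaters means the
planted coefficients are exactly the data-generating parameters that
recovery tests estimate. All randomness flows from one seed through named
substreams (colony / breeding / floaters / settlement / morphometrics), so
any one component can be regenerated alone.

What the generator does *not* emulate: female floaters, polygyny, movement
trajectories between boxes, heterogeneous detection probability among
individuals, occupancy exclusion at settlement (two floaters may pick the
same box), and natal-site fidelity. Passing tests therefore demonstrate
that the estimators recover the assumed data-generating structure, not that
real colonies satisfy it.

## Problem sizes and runtime choices

Recovery tests use 200 groups × 20 observations (Poisson), 150 crossed
groups × 3000 rows (binomial), 150 groups × 3000 (hurdle), and 500 floaters
× 246 boxes (settlement), sizes at which planted parameters are recovered
within 2 SE. The acceptance script averages the vacancy log-OR over three
replicate 500-floater colonies because a single replicate has Monte-Carlo
spread of roughly ±0.3 on the OR scale at strong distance decay. Permutation
tests default to B = 10,000; the null-calibration suite uses B = 999 × 200
replicates. The full test suite runs in a few minutes on one core.

## Known limitations

* The Laplace approximation for crossed effects is less accurate than
  quadrature when cluster sizes are tiny (few observations per floater);
  with the candidate-set design (≥5 rows per floater) the bias is
  negligible against lme4 on fixtures.
* The univariate settlement GLMM approximates what is structurally a
  conditional (one-choice-per-floater) logit; with planted effects the
  recovery is unbiased at the simulated densities but the equivalence is
  not general.
* Variance-component SEs are not reported; boundary fits (σ² → 0) are
  flagged instead.
* Ownership assignment requires the female owner to be known (from night
  reads or the breeding record); it does not infer her from data.
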