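# Methods

## The model

`marweb` infers interspecific interaction strengths in a monthly-sampled
plankton community from a first-order multivariate autoregressive (MAR)
model on de-seasoned log-abundance anomalies:

    x_t = B x_{t-1} + a + C u_{t-1} + w_t,   w_t ~ N(0, S)

* `x_t` — p×1 vector of de-seasoned, z-scored log(x+1) abundances of the
  modeled (variate) taxa at month t;
* `B` — p×p interaction matrix; `b_ij` is the effect of taxon j's density
  at month t−1 on taxon i's per-capita growth; diagonal entries measure
  density dependence;
* `a` — p×1 intrinsic rates (≈0 after z-scoring; kept free so the model
  does not lean on the preprocessing being exact);
* `C` — p×q covariate-effect matrix; covariates (invader abundances,
  water temperature) force the community at the same one-month lag as
  the variates but have no equation of their own — the natural choice
  for invaders whose dynamics are driven by their own phenology rather
  than by the modeled native community;
* `S` — process-error covariance absorbing environmental noise and
  unmodeled interactions.

Because every state is observed (after short-gap interpolation), the
conditional Gaussian likelihood given the first observation is exact; no
state-space filtering is needed. There is no separate observation-error
equation: measurement noise is absorbed into `S`.

## Preprocessing

Fixed order: counts → density (count × sample/subsample volume ratio ÷
filtered volume) → functional-group aggregation (replicates averaged per
date, then members summed) → log(x+1) → linear interpolation of interior
gaps of ≤ 1 month → monthly climatology (per-taxon mean of each calendar
month across years) → de-seasoning (raw − climatology, so positive
anomaly = above seasonal average) → z-scores using one global mean and
sample sd (ddof = 1) per series. Temperature skips the log but is still
de-seasoned — its annual cycle would otherwise swamp the covariate
signal — and z-scored. Leading/trailing gaps and gaps longer than the
limit are reported, never filled. Missingness is carried as an explicit
NaN-backed mask; transitions touching a missing value are dropped from
the likelihood rather than imputed.

The global (whole-series) z-score scope was chosen over per-calendar-
month scaling: one scale per variable keeps coefficients comparable
across taxa, and a per-month sd estimated from ~12 values per month
would be unstable.

## Estimation

Sparsity constraints are boolean masks over `B` and `C` (structurally
zero entries are exactly zero in the output). The masked likelihood is
maximized by alternating two exact updates: the masked generalized
least-squares solution of the coefficient block given `S` (a linear
solve on the free entries of kron(S⁻¹, Z′Z)), and the maximum-likelihood
update of `S` given the coefficients, projected to its declared form.
Both updates are exact coordinate-ascent steps, so the log-likelihood is
monotone; iteration stops when its relative change falls below 1e-10
(budget 10,000 iterations; with the default diagonal `S` the coefficient
update is independent of `S` and the scheme converges in two passes to
the closed-form row-wise solution). Initialization is deterministic —
the identity-weighted masked solution — so refits are reproducible.
`S` defaults to diagonal (independent process errors): with T = 144
months and p = 7 taxa an unconstrained `S` would add 21 covariance
parameters for little gain; the unconstrained and shared-variance forms
remain available. The diagonal of `S` is floored at 1e-12 so noiseless
data remain fittable.

The fully free model has a closed-form solution (row-wise least squares
with ML residual covariance); it is kept as an independent oracle and
the iterative fitter is required to reproduce it to 1e-6.

## Uncertainty

Default intervals are curvature-based: the observed information is the
negative central-difference Hessian (relative step 1e-5) of the
conditional log-likelihood in the free coefficients with `S` held at its
optimum; standard errors are the inverse-information diagonal and
intervals are estimate ± z₁₋α/₂·se. For a Gaussian model with fixed `S`
the log-likelihood is exactly quadratic, so these match the closed-form
regression covariance. A parametric bootstrap (simulate from the fitted
model conditioning on observed covariates and the first state, refit the
same structure, take percentile bounds as order statistics at ranks
⌊n·α/2⌋ and n−1−⌊n·α/2⌋) serves as the cross-check; non-converged
replicates are dropped and counted, with the result flagged above 10%
loss. A coefficient is significant when its interval excludes zero.
No multiple-testing correction is applied across the coefficient table —
intervals are per-coefficient 95% statements, and with ~40 free
coefficients a handful of false positives per table is expected; treat
borderline entries accordingly.

## Structure search

"Permuting the model structure" is implemented as deterministic greedy
backward pruning: start from the fully free model, refit every candidate
with one free off-diagonal `B` entry or `C` entry masked, accept the
pruning that most decreases AICc (k counts free coefficients plus the
free variance parameters), and stop when no pruning decreases it. Ties
break toward the lexicographically smallest coefficient address.
Diagonal `B` entries and intercepts are never pruned — every taxon keeps
density dependence — and focal covariate columns can be locked in so the
scientific question stays in the model. AICc ≈ AIC at these sample
sizes, so a truly-zero coefficient survives pruning with probability
≈ P(χ²₁ > 2) ≈ 0.16; the search is a robustness probe, not a
false-positive-free model selector, which is why significance is decided
by the confidence intervals and not by retention alone.

## Diagnostics

Per-taxon one-step residual mean, sd, lag-1 autocorrelation and the
Ljung-Box portmanteau over lags 1–12 quantify what a residual plot would
show. The stability block reports the spectral radius of `B` and, when
it is below one, the stationary covariance solving the discrete Lyapunov
equation V = B V B′ + S (scipy's solver, unit-tested against naive
fixed-point iteration).

## The synthetic generator

The generator is the package's ground-truth instrument; it emulates the
study conditions, not arbitrary data:

* 12 years × 12 months of lognormal seasonal abundance for seven modeled
  functional groups (Bosmina, Daphnia, cyclopoid copepods, Asplanchna,
  Brachionus, ciliates, autotrophs) and four covariates (temperature,
  invasive calanoid nauplii and copepodites, planktonic clam juveniles);
* anomalies drawn from the MAR recursion with the system's reported
  significant interaction strengths as generating truth (Daphnia →
  Bosmina −0.20, copepodites → Daphnia −0.21, copepodites → cyclopoids
  −0.17, nauplii → ciliates −0.18, nauplii → autotrophs −0.16,
  temperature → Bosmina 0.17 and → Daphnia 0.23, diagonals 0.19–0.41).
  Daphnia's diagonal, not significant in the source system, is set to
  0.25 — within the reported diagonal range — because the search
  protects diagonals and the truth structure must include one;
* `S` diagonal with S_ii = 1 − B_ii², putting each variate's stationary
  variance at ≈1 on the z-score scale;
* covariates built as deterministic 12-month pulse templates plus
  Gaussian noise, z-scored — the shape the fitter sees after real
  covariates are preprocessed; the invader pulses peak in August–
  September with log-scale amplitudes (7.5/7.0/6.5) that push the
  invaders above 90% of total zooplankton abundance at the peak,
  matching the invaded system's phenology;
* the state starts from the stationary distribution when the spectral
  radius of B is below one (no burn-in bias in moment checks), from zero
  with a warning otherwise;
* missing months are an explicit mask applied at the abundance level;
* the embedding inverts the preprocessing chain (seasonal log-mean
  profile + log-sd × anomaly, then expm1), so preprocess ∘ embed returns
  the anomalies exactly up to the per-month climatology constants and
  the global standardization — machine precision in practice, asserted
  at 1e-10. Embedding log-sds are 0.35 with winter baselines ≥ 20
  individuals m⁻³ so the log(x+1) level stays many standard deviations
  above zero; a level below zero would have no abundance preimage and is
  floored at a true zero count (unreachable under the defaults).

What the generator does not emulate: non-Gaussian count noise (the
observation process is absorbed into `S` on the log scale, as in the MAR
form itself), spatial structure, invader demography feeding back on the
natives, and flow/hydrology. Passing tests therefore demonstrate that
the estimator recovers MAR dynamics embedded in realistic seasonal
abundance — not that a field community is MAR(1).

## Validation studies and their sizes

`marweb.experiments` fixes the study designs (all seeded, all run by the
test suite and the acceptance script):

* oracle equivalence — 50 random stable instances, p ∈ {2,3,7},
  q ∈ {0,2,4}, T ∈ {24,144}; agreement to 1e-6 required;
* recovery — 200 replicates of the default scenario at T = 144,
  refitting the true structure; per-coefficient median error < 0.05 and
  pooled 95% CI coverage inside the 99% binomial band around 0.95
  (pooling over replicate × coefficient pairs; per-coefficient bands at
  n = 200 would make the joint test fail by chance for ~24 coefficients
  even at exactly nominal coverage);
* stationary moments — one T = 20,000 trajectory vs the Lyapunov fixed
  point, batch-means standard errors (50 batches), 3 SE entrywise;
* preprocessing invariants — month-mean-zero, unit-moment and round-trip
  checks at 1e-10 on a gap-free 12-year realization;
* structure search — 50 runs each of (i) a sparse 4-taxon truth (6 of 12
  off-diagonals nonzero, S = 0.1·I, T = 1200): complete retention of the
  true support required in ≥ 90% of runs; and (ii) diagonal-B null data
  at T = 144: spurious off-diagonal retention ≤ 20% per coefficient
  (the AICc pruning threshold implies ≈ 16%; demanding near-zero
  spurious retention would contradict the selection rule itself).

## Known limitations

Interaction estimates are covariance-based: a shared unmeasured driver
can masquerade as an interaction. Hessian intervals are asymptotic and
slightly anti-conservative at T = 144 (ML variance divisor, normal
rather than t quantiles) — observed pooled coverage ≈ 0.94. The greedy
search explores one path through structure space, not all subsets. Lags
longer than one month, observation-error state-space variants, and
regularized estimation are out of scope.
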