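# Methods

Model definitions, estimation details, default choices and their rationale,
and known limitations. Notation: each dyad contributes two aligned 0/1
streams `seq_a` (partner A) and `seq_b` (partner B) over `T_obs ≥ 2`
intervals; the expanded joint state is `s = a + 2b` with the fixed alphabet
(0 = NONE, 1 = A_ONLY, 2 = B_ONLY, 3 = BOTH).

## Data model (`seqdata`)

- **Dropout.** Missing values are allowed only as a terminal suffix
  (monotone dropout): a dyad that leaves the study contributes a shorter but
  contiguous record. Internal gaps raise `NonTerminalMissingError` rather
  than being imputed — interval-sampled behavior streams have no principled
  single-cell imputation, and silently dropping interior intervals would
  corrupt every lag-1 statistic.
- **Descriptives.** The per-interval state distribution uses the number of
  dyads still observed at that interval as the denominator. Entropy is
  Shannon entropy normalized by ln 4, so 0 means all observed dyads share one
  state and 1 means a uniform spread over the four states.
- **Frequency correlation.** The most aggregate association measure is the
  Pearson correlation between per-dyad counts of 1-intervals in the two
  streams. With unequal observed lengths the counts are not comparable and a
  warning is emitted.

## Aggregated logit APIM (`logit_apim`)

For one target partner, each dyad's lag-1 dependence is summarized in a 4×2
**state-transition table**: rows are the joint prior state at t−1 in the
order (A=1,B=1), (1,0), (0,1), (0,0); columns are (target shown, not shown)
at t. The saturated logit with effect-coded (+1/−1) lagged own and partner
behavior,

```
logit P(y_t = 1) = b0 + b_actor·own_{t-1} + b_partner·other_{t-1} + b_ixn·own·other
```

has a closed form because the model is saturated: with row log-odds
`L_s = ln((n_yes + c)/(n_no + c))`, the coefficients are the orthogonal
contrasts `b0 = mean(L)`, `b_actor = Σ own_s·L_s / 4`, etc. On all-positive
tables with `c = 0` this equals iteratively fitted maximum-likelihood
logistic regression on the grouped data (verified against an external GLM
implementation to 1e-8 in the test suite).

- **Continuity constant.** Zero cells make log-odds infinite. The default
  policy (`correct`) adds `c = 0.5` to *every* cell of *every* table, which
  keeps all dyads in the analysis and is deterministic. This shrinks
  estimates toward zero; the shrinkage decays with T (measured bias of the
  actor coefficient at a true value of 0.4: about −0.06 at T = 48, −0.02 at
  T = 200). The alternative policy (`drop`) excludes dyads with any zero
  cell and fits the rest with `c = 0`, which is near-unbiased but discards
  data. Report which policy was used.
- **Aggregation.** Per-parameter one-sample t-tests across dyads
  (df = n − 1), paired t-tests for outcome-A-vs-outcome-B contrasts over the
  dyads usable for both fits, and Welch t-tests (Welch–Satterthwaite df) for
  two-group comparisons. Odds ratios are `exp(mean β)`.

## Multilevel logistic APIM (`mlm_apim`)

Both partners' records are stacked into a long table with two rows per dyad
and interval (t ≥ 2): `dv` is the member's own behavior at t (occurrence
= 1), `ae`/`pe` are the effect-coded (±1) own and partner lagged behaviors,
and `sex` is a 0/1 member dummy (0 = reference member = stream B) moderating
all three terms — eight fixed effects in total. Dyad-level random effects on
any subset of terms have an unstructured covariance.

- **Estimation.** Laplace-approximated marginal maximum likelihood: for each
  dyad the random-effect vector is profiled out at its conditional mode
  (damped Newton, vectorized across dyads batched by record count), and the
  fixed effects plus the log-Cholesky factor of the random-effect covariance
  are optimized by L-BFGS-B. Fixed-effect standard errors come from the
  finite-difference Hessian of the marginal log-likelihood. With an empty
  random specification the model reduces to pooled logistic regression
  (verified against statsmodels to machine precision).
- **External validation.** On a simulated 60-dyad dataset, the
  random-intercept model agrees with lme4's `glmer(..., nAGQ = 1)` to about
  1e-4 in every fixed effect, the random-effect SD and the log-likelihood
  (frozen oracle values in `tests/test_mlm_apim.py`).
- **BIC.** By default the BIC sample size is the number of *dyads* (the
  level-2 units whose count drives the information about variance
  components); `bic_n="records"` is available. Because candidates with
  different random structures are not nested in a way that licenses χ²
  tests at the boundary, structure selection uses BIC only.
- **Coverage.** Laplace fixed-effect CIs are slightly liberal: calibrated
  95%-CI coverage in the recovery design used by the test suite (200 dyads ×
  48 intervals, random intercept SD 0.5) is ≈ 0.93.

## Markov family (`markov`)

All three models operate on expanded 4-state sequences and report
log-likelihood, free-parameter count and BIC.

- **Basic Markov.** Closed-form ML: the transition matrix is the
  row-normalized pooled count table; the initial distribution is the
  empirical first-state distribution. Rows for never-visited prior states
  are NaN with a warning (not silently uniform). Free parameters: 3 initial
  + 4×3 transition = 15. **Conditional actor/partner effects** are sums of
  transition probabilities, e.g. the actor effect for partner A given B was
  absent is `p(A_ONLY→A_ONLY) + p(A_ONLY→BOTH)`.
- **Hidden Markov.** Baum–Welch EM with scaled forward–backward, batched
  over equal-length sequences. `zero_mask` fixes chosen transitions at exact
  zero (e.g. an absorbing "resolved" state); EM's multiplicative updates
  preserve exact zeros, so masked cells never become positive. The best of
  `restarts` seeded random initializations is kept. Without a mask, latent
  states are canonicalized by descending initial probability; with a mask the
  user's indexing is preserved (the mask pins the meaning of the states).
  Free parameters: (K−1) initial + (unmasked transition entries − K) + K·3
  emission.
- **Mixture Markov.** EM over per-dyad sufficient statistics (first-state
  indicator and 4×4 transition counts), so the E-step cost is independent of
  T. Classes are reported sorted by descending weight; posteriors and hard
  labels are exposed for downstream validation. With one class the fit is
  identical to the basic Markov model (asserted in tests to 1e-8).
- **EM monotonicity** is asserted at every iteration (tolerance 1e-9); a
  decrease raises `AssertionError` rather than being silently ignored.
- **BIC convention.** The sample size is the total number of observed
  intervals across sequences (the likelihood includes initial-state terms).
  `compare_bic` refuses to rank models whose `n_obs` fingerprints differ.

## Optimal matching and clustering (`om_cluster`)

- **Distance.** Dynamic-programming edit distance with substitution-cost
  matrix and indel cost. Default costs are **transition-rate (TRATE)**
  based: `sub[i,j] = 2 − p(j|i) − p(i|j)` from a basic Markov fit on the same
  data, zero diagonal, range [0, 2], with unit indel.
- **Ward clustering.** Lance–Williams recurrence on *squared*
  dissimilarities; merge heights are reported on the squared scale (the
  square root reproduces SciPy's `linkage(..., 'ward')` heights exactly, and
  cuts agree — verified in tests). Ties break deterministically at the
  lowest index pair.
- **Cluster number.** Mean silhouette width over a k range (default
  2..min(8, n−1)), with per-dyad widths, merge-height scree values and 2-D
  classical (Torgerson) MDS coordinates as diagnostics. Singletons get
  silhouette 0. A mean silhouette above 0.51 sets an advisory
  `reasonable_structure` flag; no solution is auto-rejected.
- **Validation.** `agreement` maximizes the percentage of identically
  assigned dyads over all one-to-one label matchings (brute force, ≤ 6
  groups). `covariate_association` is the point-biserial correlation between
  2-group membership and a dyad covariate.

## Design and power (`design_power`)

- **`est_freq`** simulates the expected number of zero and low-frequency
  cells in a dyad's 4×2 transition table: each simulated dyad draws its
  table as i.i.d. multinomial assignments from the expected cell
  probabilities. The default number of draws is T − 1 (the number of
  transitions); `n_draws` overrides it for designs that count T observations
  instead. Reported with full count distributions and Monte Carlo SEs.
- **`est_time`** inverts this to the smallest T whose expected problem-cell
  count is at most a tolerance, using common random numbers across candidate
  T so the expected count is non-increasing in T and the doubling-plus-
  bisection search is self-consistent. Structural-zero cells make a zero-cell
  tolerance below their count infeasible (explicit error).
- **t-test sample sizes** use exact noncentral-t power (one-sample:
  df = n−1, ncp = d√n; two-sample equal groups: df = 2n−2, ncp = d√(n/2))
  and return the smallest n reaching the target power; minimality is
  verified post hoc in tests. For d = 0.80 the exact computation gives
  N = 15 for the one-sample design.
- **Correlation sample sizes** use the Fisher-z approximation
  `n = ((z_{1−α/tails} + z_{power}) / atanh r)² + 3`, rounded up; this can
  differ by about one unit from exact-distribution tables (e.g. 85 vs 84 at
  r = 0.30).

## Simulators (`simulate`)

Defaults emulate a short standardized couple-observation design: 64 dyads ×
48 intervals, initial joint-state distribution `(0.02, 0.03, 0.03, 0.92)` —
nearly all dyads start with both behaviors shown, as after a stress
induction. All randomness flows through one seeded generator per dataset, so
results are bit-identical given the seed. Optional geometric dropout is off
by default. `CoefficientHeterogeneity` adds dyad-level normal perturbations
to the logit coefficients, shared by both partners (common-fate style), so
e.g. a positive intercept draw raises both behaviors' base rates in that
dyad. The logit generator draws the two behaviors conditionally
independently given interval t−1.

## Statistical test designs

The recovery checks in `tests/test_acceptance.py` use designs fixed from
calibration runs on seed ranges disjoint from the test seeds:

- *Basic Markov* (±0.03): 5,000 dyads × T = 2 with a uniform initial state,
  i.e. exactly 5,000 transitions spread evenly over prior states — rare rows
  get enough visits for the tolerance to be a ~4-SE bound.
- *HMM* (±0.03): 500 dyads × 48 with the absorbing-state mask; the masked
  cell must stay exactly zero.
- *Mixture* (hard-label accuracy ≥ 0.8 after matching): 200 dyads × 48 from
  well-separated class dynamics.
- *Aggregated logit*: 95%-CI coverage of the generating coefficients over 40
  replicates × 4 parameters with the `drop` policy (calibrated coverage
  0.945 over 200 independent replicates); bound 0.875.
- *GLMM*: 95%-CI coverage over 10 replicates × 8 fixed effects (calibrated
  coverage 0.93 over 30 independent replicates); bound 0.85.

Single-run all-parameters-in-CI checks were deliberately avoided: with 8
parameters at 95% nominal coverage a correct implementation fails such a
check about one time in three.

## Limitations

- First-order (lag-1) dependence throughout; higher-order or semi-Markov
  dynamics are out of scope.
- Two binary behaviors only; multi-category codings would need a larger
  joint alphabet and are not implemented.
- The multilevel model uses the Laplace approximation (one quadrature
  point); with very small dyad record counts or large random-effect
  variances, adaptive quadrature would be more accurate.
- `est_freq` draws table cells i.i.d. from the expected cell probabilities
  rather than simulating a Markov chain; a chain-based simulator would
  capture serial dependence in cell counts.
- The correlation sample-size formula is an approximation (see above).
- Mixture-model class recovery assumes reasonably separated dynamics;
  labels are identified only up to permutation and are reported sorted by
  weight.
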