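# Methods

This note records the models, conventions and numerical choices behind
`cfbaudit`, and what the synthetic experiments do and do not establish.

## Population-level cfb

All population computations are exact. A discrete benefit population is a
finite covariate distribution Pr(X = x) with one probability triple
(p₋(x), p₀(x), p₊(x)) per stratum for the ternary benefit
B ∈ {−1, 0, +1}. For a predictor h, two independent draws (X₁, B₁), (X₂, B₂)
are enumerated over all (x₁, x₂, b₁, b₂) combinations and accumulated into a
3×3 table indexed by (sign(h(x₁) − h(x₂)), sign(b₁ − b₂)). The cfb reads the
B₁ > B₂ column:

    cfb = [P(H>, B>) + ½ P(H=, B>)] / P(B₁ > B₂).

Conventions, following the working definition with ties:

* Pairs tied on benefit (B₁ = B₂) are excluded from numerator and
  denominator; prediction ties among benefit-unequal pairs score ½.
* If Pr(B₁ > B₂) = 0 (benefit almost surely constant) the statistic is
  undefined and a `DegenerateBenefitError` is raised.
* Predictors are evaluated once per covariate level and cached, so prediction
  ties are decided by exact equality of stored floats and cannot be split by
  re-evaluation nondeterminism. Ties are semantically meaningful (half
  credit), so no tolerance is applied to them.
* Probability inputs are validated to 1e−12 and never silently renormalized;
  a config typo should fail loudly rather than shift every downstream number.

The sample version scores all unordered pairs of matched-pair records. The
count is exact but computed per benefit level with sorted predictions and
binary search (O(n log n)) rather than a literal O(n²) sweep; a brute-force
pairwise oracle verifies equality on small samples in the test suite.

## Improperness search

For a binary covariate with Pr(X = 1) = w₁ and triples p (X = 0), q (X = 1),
the true predictor h\* is improper (cfb\* < ½) exactly when

* ordering: q₊ − q₋ ≥ p₊ − p₋, and
* discordance dominance: Σ_{a>b} q_a p_b < Σ_{a<b} q_a p_b.

The search enumerates every ordered pair of triples with components on a
step-grid of the probability simplex (default step 0.01, i.e. 5 151 triples
and ~26.5 M ordered pairs, fully vectorized and chunked; about a second on one
core) and retains pairs satisfying both conditions, recording the exact cfb\*
of each.

**Tie-handling decision.** When the ordering condition holds with equality the
two strata have identical h\* values, and indexing the pair table by h\* alone
would make every benefit-unequal pair a prediction tie (cfb\* exactly ½). The
known minimizing grid pairs are exactly of this kind, so the search treats the
strata as *distinct prediction groups* — the pair table is indexed by the
stratum label, and of the two labelings the one with discordance dominance
(hence cfb\* < ½) is retained. The direct table computation is the arbiter;
under strict ordering the two indexings coincide. With this convention the
full 0.01-grid enumeration has median 0.4916, maximum < 0.5, and minimum
0.41737 at p = (0.01, 0, 0.99), q = (0, 0.02, 0.98), the grid point closest to
the infimum 5/12 of the family {p = (a, 0, 1−a), q = (0, 2a, 1−2a)} whose
cfb\* is (2.5 − 2.5a)/(6 − 7a).

With benefit restricted to two levels (no-effect mass forced to zero) the two
conditions are incompatible and the search is empty at every step — the
classical c-statistic for binary outcomes does not admit this failure.

The step parameter accepts values up to 0.5; coarse grids (0.2, 0.25) are
useful as fast smoke tests and already contain improper pairs.

## Counterfactual feasibility screen

A triple (p₋, p₀, p₊) arises from conditionally independent Bernoulli
potential outcomes iff π₀, π₁ ∈ [0, 1] exist with π₁(1 − π₀) = p₊ and
π₀(1 − π₁) = p₋. Substituting π₁ = π₀ + (p₊ − p₋) reduces the system to the
quadratic π₀² − (1 − d)π₀ + p₋ = 0 with d = p₊ − p₋, solved in closed form;
the second equation is then an identity. Roots are accepted within 1e−9 of
the unit interval and of the target masses (boundary cases such as
deterministic benefit land exactly on 0 or 1 up to rounding). An exhaustive
(π₀, π₁) grid oracle lives in the test suite only.

## Continuous covariate via Beta mixing

The binary covariate is the ε ↓ 0 limit of X ~ Beta(ε, ε) with linearly
interpolated conditional triples Pr(B = i | X = x) = p_i + (q_i − p_i)x. The
true predictor is affine in x, so prediction ties have probability zero when
the triples differ, and both the concordant mass and Pr(B₁ > B₂) are bilinear
in (X₁, X₂) restricted to the half-plane X₁ > X₂. The implementation therefore
needs only E[X] = ½, E[X₁X₂] = ¼ and E|X₁ − X₂| = ∫ 2F(1 − F) dx, the last
integrated adaptively (`scipy.integrate.quad`); this is exact up to 1-D
quadrature error and remains stable at ε = 0.001 where a 2-D product rule
would struggle with the endpoint-concentrated density. The Monte Carlo variant
scores floating-point ties in X as ½: at small ε, Beta samples underflow to
exactly 0 or 1, and the ½ score is precisely the binary-limit behavior (the
two estimators agree within Monte Carlo error). For the worked-example
triples the values decrease monotonically in ε through
0.49391 (ε=1), 0.49107, 0.49087, 0.4908656 (ε=0.001), approaching the binary
value 0.4908655.

## Linear-Gaussian counterfactual model

Y⁽ᵗ⁾ = α_t + β_t X + ε_t with X ~ N(0, x_sd²) and (ε₀, ε₁) bivariate normal
with sds (σ₀, σ₁) and correlation ρ. Then B = Y⁽¹⁾ − Y⁽⁰⁾ and
H\* = E[B | X] are jointly normal, pair differences remain normal, and the
bivariate-normal orthant probability gives the closed form

    cfb* = ½ + arcsin(r)/π,   r = sd(H*)/sd(B),
    sd(B)² = (β₁ − β₀)² x_sd² + σ₀² + σ₁² − 2ρσ₀σ₁.

Continuous benefits tie with probability zero, so the tie term vanishes; a
constant predictor (β₁ = β₀) returns ½ by the all-ties convention. The form
makes the two invariances obvious (location shifts in α; common positive
rescaling of β-difference, σs and x_sd) and shows cfb\* is nondecreasing in ρ
and strictly increasing whenever σ₀σ₁ > 0 — the correlation between
counterfactual outcomes, unidentifiable from any observed data, moves the
metric. The closed form is verified against a pair-sampling Monte Carlo
estimator in the tests; for thresholded (binary) outcomes no closed form is
attempted and a seeded Monte Carlo estimator is used, with the per-patient
true predictor computed analytically as a difference of normal CDFs.

## Matched populations

Source population: X ∈ {0, 1, 2} with masses (a, b, 1 − a − b) (zero-mass
levels dropped), treatment assigned with probability ½ independently of X,
and logit Pr(Y = 1 | T, X) = β₀ + β_x X + β_t T + β_xt TX. The observed
benefit of a matched treated/control pair with success probabilities (π₁, π₀)
is +1 with probability π₁(1 − π₀), −1 with π₀(1 − π₁), 0 otherwise — by
construction a distribution consistent with independent counterfactuals.

* **Match on X**: one matched level per covariate level; levels sharing a
  prediction value appear as distinct support points with tied predictions.
* **Match on H**: one matched level per distinct prediction value v; treated
  and control covariates are drawn independently from Pr(X | h(X) = v) (the
  arm-free conditional, by randomization) and the Bernoulli pair
  probabilities are mixed over (x₁, x₂). Singleton preimages reduce exactly
  to the match-on-X construction, making the bijective-predictor identity
  exact in floating point.
* **Schemes**: `sequential` (treated patient first, then a matching control)
  weights each level by its source mass and preserves the covariate marginal;
  `joint-conditional` (two independent patients conditioned on matching)
  weights by squared mass, renormalized — the marginal-distortion caveat.

The sweep samples (a, b) uniformly from the 0.01-grid combinations with
0 < a + b < 1 and draws the four coefficients from U(−5, 5), seeded,
defaulting to 10 000 combinations (a desk-scale run taking seconds; the
coefficient draws are irreproducibly random in the motivating experiment, so
only distributional properties — most |Δcfb| below 0.05, a strictly positive
maximum — are meaningful, not any specific maximum).

## Synthetic data

Generators are pure functions of (spec, n, seed) built on
`numpy.random.default_rng`; no global state. They emulate exactly the
structures the exact computations assume — categorical covariates, Bernoulli
outcomes from the logistic model, bivariate-normal counterfactual noise,
i.i.d. matched-pair draws — and none of the complications of real trials
(covariate-dependent assignment, censoring, measurement error, finite-sample
matching without replacement). Passing tests therefore validate the
implementation and the population-level mathematics, not the behavior of the
estimators on real data. Counterfactual datasets expose both potential
outcomes, which is legitimate only in simulation; `observed_view` drops the
unassigned arm to mimic what a trial records.

## Test scales and tolerances

Monte Carlo cross-checks use 10⁵–10⁶ draws and a 3-standard-error band
(binomial or Fisher-z as appropriate; sample-cfb comparisons use a
conservative doubled binomial SE to cover the dependence among the O(n²)
pairs formed from n records). Exact quantities are asserted to 1e−10 or to
the printed number of decimals. All stochastic tests are seeded and
deterministic.

## Known limitations

* The improperness search's retained set depends on the equality-tie
  convention above; alternative conventions (dropping equal-h\* pairs) leave
  the qualitative conclusion unchanged but shift the minimum (0.4308 when
  only strictly ordered pairs are kept).
* C_b is implemented as the Gini coefficient of the predicted-benefit
  distribution — a Gini-type concentration measure; no attempt is made to
  reproduce any particular published estimator of benefit concentration.
* Matching is exact on discrete values; caliper/nearest-neighbor matching for
  continuous predictors, unequal allocation ratios, and censored outcomes are out of
  scope.
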