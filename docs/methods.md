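# Methods

This note documents the models implemented in `protlca`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish.

## Latent class model and estimation

The core model is a finite mixture over `J` categorical items. Class `k`
has mixing proportion `π_k`; item `j` has response probabilities
`ρ_jrk = P(y_j = r | class k)`, with items conditionally independent given
class. The complete-data log-likelihood is maximized by EM; the package
works throughout in a "stacked" one-hot space where the E-step and M-step
are single matrix products, which keeps the bootstrap-heavy model selection
tractable on one CPU.

Numerical choices:

* **Response-probability floor** `ε = 1e-6`: after every M-step each `ρ`
  block is floored and renormalized, preventing `−∞` log-likelihoods from
  empty cells. The floor bounds every fitted probability away from 0, which
  is visible in degenerate fixtures (a "pure" class reports `ρ ≈ 1 − ε`).
* **Convergence**: EM stops when the log-likelihood gain falls below `tol`
  (default `1e-6`, absolute). The per-iteration trace is retained so the
  monotonicity of EM is a tested invariant, not an assumption.
* **Initialization**: the likelihood is multimodal, and purely random
  starts demonstrably fail when class structure is carried by a minority of
  items (the categorized-PC situation: typically only a few of 20 items are
  informative, because a K-class mean structure has rank K−1). Each fit
  therefore uses a portfolio of starts: up to three *structured* starts —
  k-means on the continuous scores the design was discretized from when the
  caller supplies them (`init_scores`), otherwise k-means on a truncated-SVD
  embedding of the centered one-hot design — plus dispersed random starts
  drawn as per-class Dirichlet response profiles. The best final
  log-likelihood wins. The structured starts are an initialization
  heuristic only; the accepted solution is always the EM fixed point with
  the highest likelihood.
* **Canonical ordering**: classes are relabeled by decreasing `π` on
  return, making all reported diagnostics invariant to label permutation.
* **Identifiability guard**: `K` may not exceed the number of distinct
  response patterns.

Diagnostics: `BIC = −2ℓ + p ln n` with `p = (K−1) + K Σ_j (R_j − 1)`;
relative entropy `E = 1 − Σ_i Σ_k (−τ_ik ln τ_ik) / (n ln K)` (defined as 1
for K = 1), with `0 ln 0 := 0`.

## Class-count selection

`select_k` fits `K = 1..k_max`, locates the BIC-minimizing `k*`, then runs
the parametric-bootstrap likelihood-ratio test of `k` vs `k+1` starting at
`k*`, stepping up while `p ≤ 0.05`. The BLRT p-value is the rank statistic
`(1 + #{LR_b ≥ LR_obs}) / (B + 1)` over `B` bootstrap datasets simulated
from the fitted `k`-class model (B = 999 by default; the packaged
demonstration configuration and the test suite use B = 99 to fit desk-scale
budgets). Bootstrap refits reuse half the starts — the bootstrap dominates
the cost — and failed replicates are redrawn up to three times, with the
effective B reported. The full decision trace (per-K table plus every BLRT)
is always returned, because the interplay of BIC and BLRT admits more than
one reading and the trace makes the decision auditable. Observed LRs are
clipped at zero: a negative LR can only arise from a local optimum at
`k+1`. The observed-data fits use the full start portfolio (including the
score-seeded start when available), while bootstrap refits use random and
one-hot-SVD starts only, since bootstrap data are generated from a fitted
LCA and satisfy its assumptions exactly.

Using more starts on the observed fits than on bootstrap refits slightly
decouples the two optimizations; at the small designs used for the null
calibration (6 binary items) the effect on the test's level was not
detectable, and the rejection rate matches the nominal 0.05 within binomial
error.

## Proteome reduction and categorization

Proteins are z-scored with the *sample* SD (so a 3-point column (1,2,3)
maps exactly to (−1,0,1)); zero-variance proteins are an error, named.
PCA uses the full SVD with a deterministic sign convention (the largest-
magnitude loading of each component is positive). Quantiles are computed by
linear interpolation between order statistics — the convention is pinned
because cutpoints are frozen bit-exactly into the serialized model. A value
equal to a cutpoint falls in the upper bin. Empty categories (possible
under heavy ties) warn but are retained.

External application projects through the intersection of protein
identifiers, standardizing the incoming matrix with the *training*
means/SDs of the shared proteins; the shared fraction must exceed a
configurable floor (default 0.8). This intersection-plus-frozen-statistics
rule is the only projection that keeps a single model: no external
statistic enters the transformation. Scores from a reduced panel are mildly
attenuated; the dropout-robustness tests quantify the effect (score
correlation > 0.95 and assignment ARI ≥ 0.8 at 10% dropout).

The categorization scheme is chosen by fitting the LCA per scheme at a fixed
candidate `K` (default 3) and taking the highest relative entropy, with ties
broken toward fewer categories then lexicographic name. Comparing entropies
at fixed `K` (rather than after per-scheme K-selection) was an open choice;
fixed `K` keeps the comparison like-for-like and the selection loop cheap.
High entropy rewards crisp assignment, not correctness — on pure noise a
crisp-but-arbitrary partition can score well, which is documented behaviour
of the criterion rather than of this implementation.

## Survival association

Follow-up is truncated administratively: times beyond the horizon (default
3 years) are set to the horizon with the event flag cleared; events exactly
at the horizon are kept. Kaplan–Meier curves, the unweighted multi-group
log-rank test, and Cox proportional-hazards fits (Efron tie handling) are
delegated to lifelines; this package owns the truncation rule, the
covariate construction (indicator contrasts against a reference cluster —
by default the cluster with the lowest crude event rate, i.e. the slowest
progressing — or z-scored continuous covariates so hazard ratios read per
SD), and Harrell's concordance of the fitted linear predictor (risk ties
count ½; a pair is usable when the shorter time is an event). Cluster-vs-
outcome models are unadjusted by default; protein-level benchmarking models
add age and sex through the same covariate interface.

## Moderated differential expression

Per-protein cell-means models on the cluster factor give residual variances
`s²_g` with `d = n − K` degrees of freedom. The empirical-Bayes prior
(`d₀`, `s₀²`) is estimated by closed-form moment matching on
`e_g = ln s²_g − ψ(d/2) + ln(d/2)`: the excess variance of `e` over
`ψ′(d/2)` is inverted through the trigamma function (Newton iteration) to
give `d₀`, and the mean of `e` gives `s₀²`. When the observed spread of
log-variances does not exceed sampling noise, `d₀ = ∞` (complete pooling).
Posterior variances `s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d)` always lie between
the raw and prior variances (a tested invariant). Contrasts are one-vs-rest
per cluster — the moderated t uses `1/n_k + 1/(n − n_k)` — with an overall
moderated F (between-cluster mean square over `s̃²`) on `(K−1, d₀+d)`
degrees of freedom supplying the per-protein p-value; the contrast
structure is a documented choice, made because cluster-specific
up-regulation is the quantity of interest downstream. Benjamini–Hochberg
adjustment is the statsmodels step-up procedure behind a validating wrapper.
A protein is flagged when `adj p < α` (0.05) and `max_k |log2FC| ≥` the
threshold (1.0; 0.7 is the conventional laxer preset), and every flagged
protein is assigned to its highest-mean cluster. Fold changes are computed
on the scale of the supplied matrix — standardized by default, log2 if raw
intensities are given — and the scale should be stated when reporting.

## Genetic-algorithm variable selection

Candidates are filtered first: missingness > 5%, non-baseline variables,
and all but one representative per declared relatedness group (kept: fewest
missing, then lexicographic). The GA then searches binary masks over the
candidates with tournament selection (size 2), uniform crossover (rate
0.8), per-bit mutation (rate 1/L), and elitism (2), population 24 over 15
generations by default. Fitness is the clustering evidence
`BIC(one-class independence) − BIC(K-class LCA)` on the chromosome's
variables (complete cases only; larger is better); a relative-entropy
fitness is selectable by id. All evaluations are cached per chromosome and
the best-ever chromosome is returned, so best fitness is non-decreasing —
a tested invariant. Note an identifiability fact that shapes what
selection can do: a *single* categorical item carries no mixture evidence
(its mixture likelihood equals the independence likelihood), so a variable
is selectable only through co-variation with other class-linked variables.

## Synthetic cohorts

The generator emulates the data situation the model assumes, with all
randomness drawn from one root seed via `SeedSequence.spawn` in the fixed
order (labels, proteins, clinical, survival):

* **Proteins**: sample `i`, protein `p` is `class shift + factor background
  + unit Gaussian noise`. The informative proteins split into K blocks;
  block `k` is shifted by `effect_size` (SD units) in class `k` — a
  one-vs-rest driver pattern that also serves the differential-expression
  stage. The background is a linear factor model (`n_factors` factors,
  loadings of magnitude `factor_strength/√q`), and the factor dispersion
  grows with class index up to `1 + factor_dispersion · effect_size`
  (sicker classes are more dysregulated). The dispersion term exists
  because a K-class homoscedastic mean structure has rank K−1, so at most
  two PCs could ever carry class signal; class-dependent spread makes the
  factor-aligned PCs informative as well, which is both more realistic and
  necessary for a 20-item categorical model to see the structure.
* **Defaults** are the study conditions used throughout the tests and the
  acceptance script: n = 379 samples, 300 proteins of which 120 are
  informative, K = 3 classes mixed (0.5, 0.3, 0.2), effect size 3 SD,
  5 factors at strength 0.25 with dispersion coefficient 0.35. These
  produce the well-separated regime the stratification method presumes
  (training/external ARI ≥ 0.9 typical); weaker settings are available for
  null and stress tests.
* **Survival**: per endpoint, event times are exponential with rate
  `baseline_hazard × endpoint scale × class hazard ratio`, the hazard
  ratios defaulting to (1, 2.3, 5.8) — magnitudes mirroring the major-CV
  contrasts this workflow is meant to detect. Censoring is an independent
  exponential whose rate is tuned by bisection (analytic censored-fraction
  formula) to the target censored fraction (default 0.70 for the primary
  endpoint), truncated at the administrative horizon (3 years). Endpoint
  scales (1, 0.75, 0.23, 0.30) give 3-year event counts resembling a
  chronic-HFrEF cohort (roughly 30% major CV events, ~10% deaths).
* **Clinical variables**: class-conditional categoricals (six invented
  baseline variables by default), with missing-completely-at-random
  injection.

What the synthetic data do **not** model: assay artifacts (plate effects,
normalization), longitudinal sampling, informative censoring, competing
risks, covariance between clinical variables beyond class membership, and
real proteome correlation structure beyond a low-rank factor model. Passing
tests therefore establish the *correctness and internal consistency* of the
pipeline under its own assumptions, not its field performance on real
cohorts.

## Problem sizes used in testing

The test suite and acceptance script scale the expensive simulations to
single-CPU budgets as the package's own study sizes: class-count selection
consistency uses 20 replicates of a 600-sample, 10-item design with B = 99;
the BLRT null calibration uses 100 replicates at n = 200 with 6 binary
items and B = 19 — the rank p-value is uniform on `{1/(B+1), …, 1}` under
the null, so the 0.05-level rejection probability is exactly 1/20 for any B
with `20 | (B+1)` and a small B loses no validity, only p-value resolution;
survival recovery uses n = 1500; the derive/apply chains run at the default
379 × 300 cohort. The library defaults remain B = 999 and 20 EM starts.

## Known limitations

* The entropy criterion for scheme selection can prefer crisp-but-spurious
  partitions on structureless data; the decision trace should be inspected.
* BIC with many-category items at n in the hundreds is conservative about
  K; the BLRT step-up carries the selection in that regime, which matches
  the intended reading but means the per-K BIC table alone can be
  misleading.
* The GA's fitness landscape is flat for variables that are individually
  informative but uncorrelated with every other candidate (see above).
* Serialized models store full double precision and round-trip bit-exactly;
  editing a model file by hand voids that guarantee.
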