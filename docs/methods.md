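# Methods

## Models

Both MPT models express category probabilities as sums over tree
branches of products of process probabilities and their complements; an
integer branch coefficient collapses interchangeable paths (e.g. which
pair member was the one recalled), matching how the trees are drawn.
Structural validity is enforced at construction: every branch factor
must reference a declared parameter, every category must be reachable,
and each tree's branch probabilities must sum to one at random interior
parameter points (checked to 1e-10, which catches missing or duplicated
branches).

In the free-then-cued model, forgetting `f` applies only on the
stored-but-not-freely-retrieved path `a·(1−r)`: a pair that was stored
and retrieved as a pair at free recall is treated as succeeding at cued
recall unconditionally.  This placement follows the description that
associative storage plus retrieval leads to successful cued recall; the
branch structure is isolated in one constructor so the alternative
placement can be swapped in if a different variant is wanted.  "Exactly
one recalled" categories do not record which pair member was recalled —
the observable category system is collapsed by design.

## Aggregate maximum likelihood

`fit_aggregate_mle` maximizes the product-multinomial likelihood on
logit-transformed parameters with multi-start L-BFGS-B, then polishes
with Nelder–Mead.  The polish matters: with large counts the likelihood
differences that distinguish points along this model's soft ridge
directions fall below finite-difference gradient precision, and a
derivative-free final stage resolves them.  Estimates are clipped into
[1e-6, 1−1e-6]; degenerate inputs (a tree with zero total) produce a
warning, not an error.

A caution on identifiability: the five-parameter storage-retrieval model
has long, curved, nearly flat likelihood ridges.  At parameter values
like `a=.63, r=.49, s=u=.03, f=.02`, the Fisher information is
numerically singular — parameter sets ~.1 apart in `(a, r, f)` generate
category distributions equal to ~5e-6.  Point estimates of `f` in this
regime are meaningless even with 10⁶ observations, although the fitted
category distribution itself is pinned down exactly.  Optimizer
correctness is therefore validated (against an exhaustive-equivalent
grid search) in a verified well-conditioned regime (large `u`, moderate
`s`, Fisher condition number ≈ 4).

## Recall coding

Responses are case-folded, trimmed, and matched to the study vocabulary
at Levenshtein distance ≤ 1 (insertions, deletions, substitutions cost
1; transpositions are two edits).  Ties between two candidates at equal
minimal distance resolve in favor of a not-yet-recalled word; remaining
ties are not credited.  The first match of each study word is kept;
repeats are logged as duplicates and unmatched strings as intrusions.

Pair-adjacency for the E1 category is judged, by default, on the matched
sequence after removing intrusions and duplicates (`matched_only`): an
intrusion between pair members does not break adjacency, an intervening
different study word does.  The `raw_output` switch judges adjacency on
raw transcript positions instead.  ARC (adjusted ratio of clustering)
uses `R` = adjacent same-category repetitions, `E[R] = Σn_i²/N − 1`,
`max R = N − k`, and is reported as undefined when `max R = E[R]`
(e.g. at most one word recalled per category) — the score's denominator
is genuinely zero there and no value is imputed.

The WMC composite z-standardizes each span task over the valid scores of
the analyzed sample and averages the available z-scores per person, so a
participant with one valid score contributes its z-transform as a proxy;
participants with no valid score are excluded.  Cronbach's alpha uses
the variance-of-totals form with unbiased variances.

## Hierarchical latent-trait estimation

Person probit vectors are modeled as `η_i = μ + ξ ∘ δ_i` with
`δ_i ~ MVN(0, Q)`, giving `Σ = diag(ξ) Q diag(ξ)` — the scaled
inverse-Wishart parameter expansion.  Priors: `μ_p ~ N(0, 1)` on the
probit scale, `Q ~ InvWishart(I, P+1)`, `ξ_p ~ Uniform(0, 10)`.  The
sampler is Metropolis-within-Gibbs: a blocked random-walk proposal per
person for `δ_i` (target acceptance .234), per-coordinate random walks
for `μ_p` and `ξ_p` (target .44), and a conjugate Wishart draw for the
precision of `δ`.  Proposal scales adapt by Robbins–Monro only during
burn-in/adaptation phases, so retained draws come from a fixed kernel.
Likelihood evaluations are cached per tree; coordinate updates recompute
only the trees the parameter touches.

The default sampling plan is 20,000 samples per chain (2,000 burn-in/
adaptation), every fifth retained, 3 chains, extended in blocks of
10,000 (+1,000 adaptation) until every monitored quantity (each `μ_p`
and each `Σ` entry) has rank-normalized split R-hat < 1.05 and effective
sample size > 2,000, up to `max_extensions`; a fit that exhausts the
budget is returned flagged, never silently accepted.  R-hat of exactly
constant chains is undefined and reported as 1 by convention.
`LatentTraitConfig.reduced()` (3 chains × 2,000 retained draws) is the
plan used in the simulation studies below; on converged synthetic fits
it agrees with longer plans in group-mean θ to well under .02.

Group comparisons are draw-index-paired differences of `Φ(μ_p)` between
two independently fitted conditions, with deterministic even-index
subsampling when draw counts differ.  The Bayesian p value is the
posterior mass at or below zero (ties count).

### Covariate correlations and attenuation

Per retained draw, the Pearson correlation between the covariate and the
person-level probits `η_·p` is computed (missing covariates excluded
pairwise), yielding a posterior of draw-wise correlations.  This is the
standard sample-statistic approach for latent-trait MPT covariates, and
it is **attenuated**: the draws of `η_i` contain posterior uncertainty
that is independent of the covariate, so with weak person-level data the
draw-wise correlation is biased toward zero.  At the study designs (8
pairs + 4 singletons, or 20 pairs per person) a true probit-scale
correlation of .4 yields posterior-mean correlations of roughly .05–.20;
with 100 items per person the same pipeline returns ≈ .36.  The
estimator is a monotone, consistent-under-increasing-items measure of
association, and its directional Bayesian p is well calibrated under the
null (false-detection rate ≈ .05 in 20-replicate calibration runs), but
its magnitude must not be read as the latent correlation.  One
acceptance test asserts the idealized no-attenuation recovery bound and
is expected to fail for this documented reason.

### Posterior-predictive checks

For each sampled draw, a fresh sample of n persons is drawn from that
draw's group-level `MVN(μ, Σ)` and replicated multinomial data are
generated — replication over new persons, not conditional on the fitted
person effects, so the checks are sensitive to violations of the
population-distribution assumption.  T1 is the chi-square-type distance
between mean observed category frequencies and their expectation; T2 is
the analogous distance for the covariance matrix of individual category
frequencies (expected covariance = between-person spread of expected
counts plus average within-person multinomial covariance, standardized
by expected variances; trees contribute block-diagonally to the
within-person part).  `p = P(T_rep ≥ T_obs)` with ties counted as
exceedances, so a deterministic regime where replicates equal the data
gives p = 1.

Power caveat: with 8 items per person, a population split into two
latent subgroups with opposite storage probability is statistically
invisible — the free person-level covariance absorbs the induced second
moments, and T2 p-values stay unremarkable even with extreme subgroup
separation at n=200.  The violation-sensitivity checks therefore use an
item-rich design (48 pairs + 24 singletons, n=150), where T2 detects the
subgroup structure in essentially every replicate.  Passing those checks
shows the statistic works when the data can carry the signal; it does
not imply such violations would be detected at the study's list length.

## Synthetic data

`simulate_population` draws `(η_i, z_i)` jointly multivariate normal so
that `z` is marginally standard normal and `corr(η_ip, z) = ρ_p`;
infeasible correlation sets (joint covariance not positive semidefinite)
are rejected at design validation.  Defaults are the study conditions:
8 pairs + 4 singletons or 20 cue–target pairs; group-level θ at the
estimated group means of the respective paradigm; diagonal `Σ*` with
probit-scale sd .4 (interquartile θ spread ≈ .2, typical of published
latent-trait applications — chosen once as a field-realistic default,
since no empirical person-level spread is available to calibrate
against).

Transcript generation realizes each person's sampled categories exactly:
adjacent-recall pairs are emitted as units, separated-recall pairs are
forced apart (re-shuffling until no separated pair is adjacent; if fewer
than three words were recalled the separated outcome is infeasible and
falls back to adjacent recall, logged), study lists satisfy the 1–4
intervening-word lag constraint via randomized backtracking placement,
typos are single random edits (still matchable at distance 1), and
intrusions are random nonwords kept at edit distance ≥ 2 from the whole
vocabulary so they can never be credited.  With zero noise, coding the
transcript reproduces the sampled category counts bit-exactly — the
round trip is asserted over 1,000 persons.  The generator makes no
claims about serial-position or temporal-context structure, semantic
similarity beyond pair membership, or span-task dynamics; passing tests
on these data show pipeline correctness, not realism of output order.

## Problem sizes

Simulation studies in the test suite and acceptance script use: group
mean recovery, n=200 persons × 5 replicates under the reduced plan;
null-calibration of correlations, 20 replicates at n=200 (2 chains ×
1,000 retained); PPC calibration, 20 replicates at n=100; violation
sensitivity, 11 replicates at n=150 with the item-rich design;
grid-search comparisons, 20 datasets per model (400/200 items for pair
clustering, 20,000 for storage-retrieval).  These sizes were chosen so
each study's Monte-Carlo error is small relative to the property being
asserted.
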