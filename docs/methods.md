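# Methods

## The model family

Bounded-count data — `y_i` successes out of `n_i` trials — are routinely
overdispersed relative to the binomial: the Bernoulli outcomes inside a
count are correlated (litter effects, clustered cells), covariates are
missing, outliers contaminate the sample, or zeros are in excess.  The
beta-binomial (BB) handles the first cause with one extra parameter: if
`pi ~ Beta(mu, phi)` in mean–precision form and `Y | pi ~ Bin(n, pi)`,

    E[Y] = n mu,
    Var(Y) = n mu (1 - mu) [1 + (n - 1) / (phi + 1)],

and `theta = 1/(phi+1)` is simultaneously the overdispersion parameter
and the intraclass correlation (ICC) of the underlying Bernoulli trials.

The flexible beta-binomial (FBB) replaces the beta mixing density with a
structured two-component beta mixture (the flexible beta): components
share the precision `phi` but have distinct means `lambda1 > lambda2`.
In the variation-independent parameterization `(mu, w, phi, p)` — overall
mean, normalized component distance, precision, mixing weight, with

    lambda1 = mu + (1-p) w min(mu/p, (1-mu)/(1-p)),
    lambda2 = mu -   p   w min(mu/p, (1-mu)/(1-p)),

the pmf is the mixture `p BB(n, lambda1, phi) + (1-p) BB(n, lambda2, phi)`
and the variance gains a cluster term:

    Var(Y) = n mu (1-mu) [1 + (n-1)/(phi+1) + (n-1) (phi/(phi+1)) w^2 m(mu, p)],
    m(mu, p) = min{ mu(1-p) / (p(1-mu)),  (1-mu)p / ((1-p)mu) }.

The ICC becomes `rho = theta + (1-theta) w^2 m(mu,p)`: a weighted
compromise between the BB correlation and the separation of the latent
clusters.  The BB is an inner point of the family
(`mu = p`, `w = 1/(nu+1)`, `phi = nu+1` reproduces `BB(n, mu, nu)`), and
the ordering `lambda1 > lambda2` holds by construction, so the mixture is
identifiable — no label switching is possible.

Regression attaches covariates through `g(mu_i) = x_i' beta` (logit by
default; probit and complementary log-log are provided behind the same
interface).  The second component is free to absorb a latent group — an
excess of zeros, a cluster of outliers — automatically and only when the
data demand it, which is the practical advantage over ad hoc
zero-inflated models (also implemented here as baselines: ZIBin and ZIBB
with inflation probability `q`).

## Priors

* `beta_j ~ N(0, 100^2)` independently ("diffuse" made concrete; the
  standard deviation is configurable through `PriorSpec`).
* `theta = 1/(phi+1)`, `w`, `p`, `q ~ Uniform(0,1)`.  The uniform on
  `theta` induces the proper density `1/(phi+1)^2` on `phi` without
  hyperparameters.  The prior for the inflation probability `q` is our
  own choice (uniform), documented here as an assumption.

## Posterior computation

All sampling happens on an unconstrained scale — `beta` untransformed,
logits of `theta`, `w`, `p`, `q` — with the exact log-Jacobian added, so
the open parameter space is never hit at its boundary.

The default backend is an **adaptive random-walk Metropolis** sampler:
all chains advance simultaneously through one batched log-posterior
evaluation per iteration; during warm-up each chain adapts a proposal
covariance by Welford updates (Haario-style) and a global step size
toward the 0.234 acceptance target; adaptation freezes when warm-up
ends, so retained draws come from a valid Markov chain.  The backend is
pluggable behind the single `fit` contract — any callable producing
`(chains, retained, dim)` unconstrained draws can replace it — and the
tests pin down the contract, not the engine.

Warm-up includes an **exploration/re-centring phase** (first third of
warm-up, capped at 500 steps): chains start from prior-random points
(`beta` from a tighter N(0,2) to avoid saturating the link) and are then
re-initialized, with proposal-scaled jitter, around the best point any
chain has found, after which adaptation restarts.  Without this, an
isolated chain occasionally settles in a minor mode of the mixture
posterior (typically `theta -> 0` with two near-degenerate components)
that a random-walk kernel cannot leave, corrupting pooled-draw summaries
and WAIC.  The re-centring lives entirely in the discarded warm-up.  Its
cost is that between-chain disagreement no longer probes genuinely
separated posterior modes; for this family that risk is limited because
the component ordering removes label-switching multimodality.

Defaults mirror standard practice for these models: 4 chains, 10 000
iterations each (20 000 in the `real-data` preset), 50% warm-up,
thinning 1.  The `reduced` preset (4 × 3 000) is the package's
scaled-down setting for replication studies on a single core; every
replication table records the scale it used.

Convergence is reported per parameter: split-R̂ and bulk ESS (via
arviz), a Geweke z-score (first 10% vs last 50%, batch-mean standard
errors), and a Heidelberger–Welch stationarity verdict (Schruben's
Brownian-bridge Cramér–von Mises test at alpha = 0.05, discarding
initial 10% increments up to 50%).  With a single chain, R̂ falls back
to split halves and the report says so.

## Model diagnostics

* **WAIC** on the deviance scale, `-2(lppd - p_waic)`, with `lppd` from
  column-wise log-mean-exp of the `B x N` log-likelihood matrix and
  `p_waic` the unbiased (`B-1` denominator) column variance.  A
  leave-one-out estimate (`-2 * sum_i log CPO_i`) is provided as a
  cross-check; the two agree closely on well-behaved fits.
* **CPO** per observation as the harmonic mean of per-draw likelihoods,
  computed through log-sum-exp; observations with natural-scale CPO at
  or below 0.01 are conventional outlier candidates.
* **Posterior predictive checks** with discrepancies: mean, variance,
  proportion of zeros, and deviance.  The deviance discrepancy is
  defined here as `-2 sum_i log f(y_i; eta_b)` against the same quantity
  on the replicate drawn at `eta_b` (the usual realized-vs-replicated
  construction; "deviance" has no unique definition for these checks, so
  this choice is documented).  p-values near 0.5 indicate a healthy fit.
* **Model selection**: strictly lower WAIC wins; exact ties are reported
  as ties, never silently awarded.

## Simulation studies and what they emulate

The generators reproduce three study designs at configurable scale:

1. *Model fit* (`N = 150`, `x ~ U(-1,1)`, `n_i ~ Poisson(200)`,
   `logit(mu) = 1 + 3x`): scenario (1) generates from a BB regression
   with `phi = 100`; scenario (2) from an FBB regression with
   `phi = 2.333`, `p = 0.5`, `w = 0.75`; scenarios (3)/(4) from generic
   two-component BB mixtures.  The generic mixtures' component means are
   under-determined by their usual description (only the precisions and
   weight are standard), so this package constructs them as logit-scale
   shifts `+/- delta` (default 0.5) around the regression line; numbers
   from scenarios (3)/(4) are therefore illustrative, not reference
   values.
2. *Excess of zeros* (`N = 100`, `n_i ~ Poisson(50)`, `x ~ U(-1.5, 2)`,
   `logit(mu) = 1 + 2x`): a chosen percentage (5/10/20/50%) of binomial
   outcomes is forced to zero.  The FBB's lower component absorbs the
   zero group, so the posterior mean of `p` tracks the unchanged
   fraction.
3. *Outlier contamination* (same binomial design): three responses are
   flipped `y -> n - y` in the lower covariate tail (scenario I), upper
   tail (II), or three in each tail (III); whether flips are drawn with
   or without replacement from a tail is unspecified in the usual
   description — this implementation samples without replacement.
   Contaminated points keep markedly higher CPO under the FBB fit than
   under binomial or BB fits.

Poisson trial counts of zero are resampled so every unit has at least
one trial (negligible probability at the default means, but the
generators are total).

These generators emulate the clean stochastic structure of the designs
— exact covariate and trial-count laws, exact contamination rules.  They
do not emulate features of real datasets such as covariate measurement
error, non-Poisson trial counts, informative cluster sizes, or
model-misspecified link functions, so passing the replication checks
demonstrates correctness of the machinery under the stated conditions,
not robustness to everything field data can do.

## Problem sizes and numerical choices

Replication studies default to R = 25 (model fit) and small seeded
replicate sets for the zero-excess fits, with the `reduced` chain
preset; these sizes keep a full desk run in minutes while holding the
Monte-Carlo standard error of a mean WAIC to a few units and of a
posterior mean of `p` to about 0.01–0.02.  Study-scale settings
(R = 1000 / 250, 10 000-iteration chains) are available through
`ScenarioConfig` and `SamplerConfig` and every output labels its scale.

Other numerics: all pmfs are evaluated in log space via `gammaln` /
`betaln` (rising factorials as `lgamma` differences, never iterated
products); mixtures combine with log-sum-exp; open intervals carry an
epsilon guard (1e-12) at the public API while the sampler's transforms
make the boundary unreachable; inverse links clamp means to
`[1e-10, 1 - 1e-10]`; `y_i = 0` and `y_i = n_i` are valid observations
for every family with no continuity correction; invalid parameter
vectors yield `-inf` log posterior (a rejected state), never an
exception.  `m(mu, p)` needs no tie-breaking: the two arguments of the
min are reciprocals and the value at `mu = p` is exactly 1.

## Known limitations

* The random-walk backend mixes more slowly than a gradient-based
  sampler; effective sample sizes per iteration are correspondingly
  lower, which the ESS column of the convergence report makes visible.
* Quantile functions and moment-based estimators are out of scope, as
  are random effects, covariate-dependent `phi`/`w`/`p`, and
  multivariate extensions.
* CPO uses the harmonic-mean estimator, which can be unstable when the
  posterior barely covers an observation; the impossible-observation
  guard (CPO set to 0 with a warning) is a coarse backstop.
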