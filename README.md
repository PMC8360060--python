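# fbbreg

Bayesian regression for overdispersed binomial data, built on the
**flexible beta-binomial (FBB)** distribution — a structured
two-component beta-binomial mixture — with binomial, beta-binomial (BB),
and zero-inflated baselines, a full diagnostic suite (WAIC, CPO,
posterior predictive checks), and simulation-study harnesses.

## Who this is for

Biostatisticians and epidemiologists modelling bounded counts — `y_i`
successes out of `n_i` trials (parasitized eggs, aberrant cells, fetal
deaths per litter) — where the binomial model underestimates the
variance.  The classical remedy, the BB model, adds a single precision
parameter `phi` whose reciprocal-plus-one, `theta = 1/(phi+1)`, is the
intraclass correlation (ICC) of the Bernoulli outcomes.  One parameter,
however, cannot absorb several *concomitant* causes of overdispersion:
latent subpopulations, clusters of outliers, or an excess of zeros.

## The model

The FBB compounds a binomial with a flexible beta: a mixture of two beta
densities with common precision `phi` and means `lambda1 > lambda2`,
parameterized by the overall mean `mu`, a normalized component distance
`w` in (0,1), and mixing weight `p`:

    f_FBB(y; mu, w, phi, p) = p f_BB(y; lambda1, phi) + (1-p) f_BB(y; lambda2, phi)

    lambda1 = mu + (1-p) w m*,   lambda2 = mu - p w m*,
    m* = min(mu/p, (1-mu)/(1-p))

    Var(Y) = n mu(1-mu) [ 1 + (n-1)/(phi+1) + (n-1) (phi/(phi+1)) w^2 m(mu,p) ]
    rho_FBB = theta + (1-theta) w^2 m(mu,p)          (the ICC)

The extra variance term captures a second latent cluster; in regression
(`logit(mu_i) = x_i' beta`) that cluster adapts *automatically* to zero
groups or outliers, without ad hoc inflation parameters.  Inference is
Bayesian (adaptive MCMC on an unconstrained scale; uniform priors on
`theta`, `w`, `p`, diffuse normals on `beta`); models are compared by
WAIC, and checked with CPO and posterior predictive p-values.  See
`docs/methods.md` for the full account.

## Worked example

`examples/04_excess_zeros.py` zeroes 5/20/50% of binomial outcomes
(`N = 100`, `n_i ~ Poisson(50)`, `logit(mu) = 1 + 2x`) and fits the FBB
regression:

```
zeroed   5% of outcomes (5 units):  posterior mean p = 0.992 (unchanged fraction 0.95), w = 0.995
zeroed  20% of outcomes (20 units): posterior mean p = 0.953 (unchanged fraction 0.80), w = 0.996
zeroed  50% of outcomes (50 units): posterior mean p = 0.515 (unchanged fraction 0.50), w = 0.994
```

The mixture's lower component absorbs the zero group: `p` estimates the
weight of the unchanged data and `w ~ 1` says the two components are
maximally separated.  `examples/03_model_comparison.py` runs the same
machinery on two-cluster data:

```
       binomial: WAIC   14895.1   PPC p-values: mean=0.50  variance=0.00 ...
  beta-binomial: WAIC    1062.9   PPC p-values: mean=0.53  variance=0.46 ...
            fbb: WAIC    1053.1   PPC p-values: mean=0.58  variance=0.32 ...
```

— the binomial fit fails the variance check outright (p-value 0.00: it
cannot reproduce the observed dispersion), and the FBB attains the
lowest WAIC.  The other examples cover the distribution itself
(`01_distributions.py`), parameter recovery (`02_fit_fbb_regression.py`),
and CPO-based outlier detection (`05_outliers_cpo.py`).

A thin CLI wraps the same functions for shell use:

```sh
fbbreg simulate scenario.yaml --seed 42 --out data
fbbreg fit data.csv --family fbb --seed 1 --out fit
fbbreg replicate scenario.yaml --seed 3 --out rep
fbbreg check data.csv --family fbb --seed 1
```

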