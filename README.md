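# bayesmr

Bayesian multi-instrument Mendelian randomization (MR) with pleiotropy-robust
shrinkage priors, a two-exposure mediation extension, the standard frequentist
comparators, and a full simulation harness for coverage/power benchmarking.

## Who this is for

Mendelian randomization uses genetic variants as instrumental variables to
estimate the causal effect of an exposure X on an outcome Y from observational
data, despite unmeasured confounding.  The classical assumptions fail when
instruments are *pleiotropic* — when a variant affects the outcome through a
path not mediated by the exposure.  This package is for analysts with
individual-level data (one continuous outcome, one or two continuous
exposures, J allele-dose instruments coded 0/1/2) who want causal estimates
that remain honest when an unknown subset of their instruments is pleiotropic.

## The model

For individual i with dose vector Z_i, exposure X_i, outcome Y_i and a latent
standard-normal confounder U_i:

    X_i | Z_i, U_i ~ N(omega_X + sum_j alpha_j Z_ij + delta_X U_i, sigma_X^2)
    Y_i | X_i, Z_i, U_i ~ N(omega_Y + theta X_i + sum_j beta_j Z_ij + delta_Y U_i, sigma_Y^2)

theta is the causal effect of interest, alpha_j the instrument strengths and
beta_j the pleiotropic (direct) effects.  Marginalizing U gives a bivariate
normal likelihood with error covariance

    [[delta_X^2 + sigma_X^2,   delta_X delta_Y      ],
     [delta_X delta_Y,         delta_Y^2 + sigma_Y^2]]

which is what the sampler targets — no per-individual confounder is ever
sampled.  The model is not point-identified from the observed moments; a
proper posterior for theta is obtained by placing a sparsity prior on the
pleiotropic effects, by default the horseshoe

    beta_j | phi_j ~ N(0, phi_j^2),  phi_j ~ C+(0, gamma),  gamma ~ C+(0, 1),

whose shrinkage weights kappa_j = 1/(1 + phi_j^2) follow a Beta(1/2, 1/2) law
a priori: small beta_j are shrunk hard to zero while genuinely pleiotropic
instruments are left nearly untouched.  A Laplace prior and the beta = 0
(classical IV) restriction are available alternatives.  Instrument strengths
get an exchangeable N(mu_alpha, sigma_alpha^2) prior with flat hyperpriors;
everything else is flat.  Posteriors are sampled with a blocked Gibbs scheme
(exact conjugate updates for all regression coefficients and the shrinkage
hierarchy, slice updates for the error-covariance parameters).

The two-exposure variant adds a mediator: X1 -> X2 -> Y with direct effect
theta1, mediator effects theta2 (X1 on X2) and theta3 (X2 on Y), giving the
indirect effect theta2*theta3 and total effect theta1 + theta2*theta3.  With
zero pleiotropy and scalar instruments these are identified in closed form by
path-tracing moments, which the package exposes as an independent
cross-check (`moment_solve_no_pleiotropy`).

Frequentist comparators: per-instrument ratio estimates, the interpolated
weighted median estimator (WME) with either an individual-level nonparametric
bootstrap or the standard summary-level parametric bootstrap, and Egger
regression (slope = causal estimate, intercept = mean directional
pleiotropy).

## Worked example

`examples/01_single_exposure_fit.py` simulates a dataset of n=500 individuals
and J=60 instruments with 40% pleiotropic instruments, balanced pleiotropy
and a true causal effect of 0.35, then fits the horseshoe model:

```
true theta            : 0.35
naive OLS slope       : 0.820  (confounded by theta + lambda/tau_X^2)
posterior mean theta  : 0.410
95% credible interval : [0.289, 0.533]  (R-hat 1.013)
```

The naive regression of Y on (X, Z) is badly biased (the confounder
contributes lambda/tau_X^2 ≈ 0.5 to the slope); the posterior brackets the
truth.  The other example scripts cover the frequentist comparators,
mediation (direct/indirect/total effects), LD-calibrated genotype simulation,
and the scenario replication harness — each prints its numbers with a note on
what they mean.

A thin CLI wraps the same functionality:

```bash
bayesmr simulate --scenario 3 --theta-regime alternative --seed 1 --out d.tsv
bayesmr fit --data d.tsv --chains 2 --warmup 500 --iterations 500 --seed 2
bayesmr wme --data d.tsv --seed 3
bayesmr evaluate --scenario 11 --methods wme --reps 100 --seed 4
```

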