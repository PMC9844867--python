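# Methods

## Model

One row per encounter.  For visit i of patient j at site k,

    g(E[y_ijk | b]) = x_ijk' beta + w_ijk' alpha_k + z_ijk' b,
    b_k ~ N(0, B_k(gamma_k)),

with common fixed effects beta, site-specific fixed effects alpha_k, and
random effects b.  The implementation supports intercept-only random effects,
one per grouping factor (patient; optionally physician, crossed), so
B_k is diagonal with one variance per factor.  Links: logit (Bernoulli
outcome) and identity (Gaussian outcome).  For the identity link the
residual variance is treated as one more element of gamma_k, so the whole
second-stage parameter is delta_k = (alpha_k, gamma_k).

Homogeneity flags make alpha and/or gamma shared across sites, in which case
the shared block appears exactly once in theta = (beta, delta_1, ...,
delta_K) and every site's derivative contributions accumulate into it.

### Variance-component parameterization

Variances are stored as eta = log(gamma) (and log residual variance), so all
outer optimization and every federated Newton step is unconstrained; the
bijection back to the covariance matrix is B(gamma) = diag(exp(eta)) per
factor.  Reported covariances for the eta coordinates are on that log scale.
Working values of eta are kept in [-12, 6]: exp(-12) ~ 6e-6 is an
effectively-zero variance, and the marginal likelihood is exponentially flat
in eta below that, which only destabilizes derivative-based steps.

## Laplace approximation

The site log-likelihood integrates the random effects out.  With
q(b) = log p(y | b) + log p(b) and b_hat = argmax q,

    lhat = q(b_hat) + (n_b / 2) ln(2 pi) - (1/2) ln det(-grad^2_b q(b_hat)).

The (n_b/2) ln(2 pi) constant of the Gaussian integral is included, which
makes the approximation *exact* for the identity link (the value equals the
marginal normal log-density with covariance Z B Z' + sigma^2 I); without it
the Gaussian identity and the small-variance GLM limit would be off by a
constant.  The constant affects no derivative or argmax.

**Inner solver.**  b_hat is found by Newton's method with step halving on
the concave q; for the identity link one linear solve is exact.  The negated
inner Hessian A = Z' W Z + B^{-1} is diagonal for a single grouping factor;
for two crossed factors it is a 2x2 block matrix with diagonal blocks,
factorized by a Schur complement on the smaller factor (cost ~ n_small^3 +
nnz); three or more factors fall back to a dense Cholesky.  Convergence
tolerance is 1e-11 on the max-norm of grad_b q, budget 100 iterations.  The
tolerance is deliberately much tighter than the inner-solver literature
default: the log-determinant term is first-order sensitive to the mode
error, and a 1e-8 tolerance leaves ~5e-9 noise in lhat — enough to corrupt
finite-difference Hessians.

**Outer derivatives.**  The gradient and Hessian of lhat over (beta,
alpha_k, eta_k) are central finite differences of lhat (relative steps 1e-4
for the gradient, 1e-3 for the Hessian, four-point cross terms).  The
evaluation at the center is always started from b = 0, so the result is a
deterministic, bit-stable function of the data and the parameter value —
this is what makes file-mediated federation reproduce in-memory runs
exactly; the perturbed evaluations warm-start from the center's mode.
Derivatives agree with independently coded central differences at a coarser
step to better than 1e-4 in relative Frobenius norm (asserted in tests).

## Local and pooled fits

`local_fit` maximizes one site's lhat: starting values for the fixed effects
come from an ordinary GLM (statsmodels), log-variances start at log(0.5);
L-BFGS-B within the box above, then a projected damped-Newton polish using
the finite-difference Hessian until the KKT gradient max-norm is <= 1e-8.
A site whose outcome is constant under the logit link (or whose information
matrix is not invertible) is refit with a ridge penalty 1e-4 ||(beta,
alpha)||^2 and flagged — degenerate sites are reported, never dropped.
V_k is the beta block of the inverse observed information.

`pooled_fit` — the gold standard every federated run is measured against —
maximizes the sum of all sites' lhat over the full theta with the same
two-stage scheme (the global gradient/Hessian assemble per-site blocks by
scatter-add).

## Federated algorithm

1. Local fits; the coordinator sets beta_bar by matrix-weighted
   inverse-variance meta-analysis (singular-V_k sites are dropped from the
   average, their delta_k still initializes their own block; shared blocks
   under homogeneity flags are combined by the same rule).  Initial
   log-variances are floored at -2.0: a local variance pinned at zero is a
   boundary artifact of a small or rare-event sample, and starting the
   surrogate expansion in the exponentially flat region leaves the
   coordinate unrecoverable.  The floor changes the starting point only.
2. Each site ships s_k (gradient), H_k (Hessian, symmetric) and lhat_k at
   the current theta — p_k + p_k(p_k+1)/2 + 1 numbers, no row-level data —
   together with a SHA-256 digest of the evaluation point, which the
   coordinator verifies before assembly (protocol-drift detection for
   manual transfers).
3. The coordinator assembles the quadratic surrogate (tangent to the global
   log-likelihood to second order) and maximizes it: a Newton step solved
   through the arrow structure — Schur complement on the shared block,
   back-substitution per site.

Steps 2–3 repeat until the L2 step norm Delta <= d (default 1e-6) or T
iterations (default 5) are spent.  Var(theta_Fed) = (-H_Fed)^{-1}, with
H_Fed re-evaluated at the final iterate.

### Step safeguarding

Far from the optimum — typically in the variance blocks of rare-event
sites — the negated surrogate Hessian can be indefinite or nearly singular.
The policy, each part flagged in the run's warnings:

* if the structured Cholesky fails, the step is computed from the
  eigendecomposition with negative eigenvalues flipped and a curvature
  floor (saddle-free Newton);
* each step coordinate is capped at 2.0 in absolute value.  Capping
  coordinates individually matters: rescaling the whole step to a norm
  budget lets one flat log-variance direction wipe out the progress of the
  informative coordinates, which in practice produced oscillation instead
  of convergence;
* updated log-variances are clamped to [-12, 6].

None of the safeguards are active in the neighborhood of a healthy optimum,
so fixed-point behavior (one iteration from the pooled optimum moves theta
by < 1e-6) is preserved.

## Data splitting (centralized use)

`random_split` permutes patients and deals them into m balanced subsets, so
all encounters of a patient stay together.  With crossed physician effects
no partition can keep both factors intact; `cluster_split` builds the
physicians' patient-sharing network (edge weight = number of distinct
shared patients) and greedily merges the heaviest-connected clusters under
a load cap of 1.25x the even encounter share until m clusters remain,
leftovers going to the least-loaded bins; ties break on (weight,
lexicographic cluster id), so the plan is deterministic.  Rows follow their
physician; a patient seen across subsets gets an independent random-effect
level in each — the approximation a split necessarily accepts, measured by
`split_quality` (fraction of same-patient and same-physician encounter
pairs co-assigned).

## Synthetic data generator

Per site k: patient count uniform on [100, 450] (defaults), 5 encounters
per patient, and

    logit P(y=1) = beta0 + x1 + 0.5 x2 + 0.5 x3 + alpha_k x4 + b_jk,
    x1 ~ Bern(p_x), x2 ~ U(0,1), x3 ~ Bern(0.5), x4 ~ N(0,1),
    b_jk ~ N(0, gamma_k).

alpha_k are K evenly spaced values spanning [0, 1] and gamma_k K evenly
spaced values spanning (0, 2] (exact zero is excluded because it is
degenerate under the log parameterization), both shuffled by the
configuration's master seed so a configuration is a fixed study design.
Covariates are redrawn per encounter (per-patient exposure available as a
flag).  beta0 is solved by root-finding on a fixed-seed 1e5-draw Monte-Carlo
estimate of the marginal outcome prevalence under the full generative
model, so a target prevalence p_y in (0.01, 0.5) maps to a deterministic
intercept.  Everything is reproducible byte-for-byte given (config, seed);
per-site streams are spawned from one seed sequence.

The crossed variant adds physician random intercepts with community
structure: physicians are divided into communities, each patient has a home
community, and each encounter's physician is drawn from the home community
except with probability `cross_prob` from all physicians.  The experiment
harness uses 400 patients, 40 physicians in 8 communities, 5%
cross-community encounters and patient/physician variances of 1.0 each —
sizes chosen so a desk-scale run exercises the same mechanism (community
structure in patient sharing) the splitting strategy targets.

**What the generator does not emulate:** informative cluster sizes,
covariates correlated with the random effects, missing data (the reader
applies the complete-case filter), non-logistic outcomes in the experiment
harness, and site-level confounding beyond (alpha_k, gamma_k).  Passing
tests therefore demonstrate the estimator's agreement with the pooled fit
and the documented failure modes of meta-analysis and random splitting —
not robustness to model misspecification.

## Experiment harness and scaling choices

`run_bias_grid` reports, per (p_y, p_x) cell and replicate, the relative
bias |estimate − pooled| / |pooled| of the exposure coefficient for the
meta-analysis and for the federated estimator after 1, 2 and 5 iterations
(one run with the trace recorded; the convergence threshold is disabled so
every iterate exists).  `run_split_scaling` simulates one 1,000-patient
dataset per replicate (5,000 encounters; exposure prevalence 0.05, outcome
0.25, alpha = 0.5, gamma = 1 held homogeneous), splits it into m subsets
and compares meta-analysis and federated estimates against the pooled fit
on the unsplit data.  Default replicate counts in the test suite and the
acceptance script (10–20 per condition) and the 1,000-patient scaling
dataset are the package's desk-scale study sizes; the harness accepts
larger values.

## Known limitations

* Random intercepts only (no random slopes); diagonal B per factor.
* Logit and identity links; the architecture takes other one-parameter
  exponential families but none are implemented.
* Outer derivatives cost O(p_k^2) likelihood evaluations per summary; fine
  for tens of parameters, not for hundreds.
* The federated loop has no line search (it would cost an extra
  communication round), so convergence from very poor initializations
  relies on the safeguards above.
* Variance-component covariances are reported on the log scale; no
  delta-method back-transform is applied.
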