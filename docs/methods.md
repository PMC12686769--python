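# Methods

This note records the models, the estimation machinery, the synthetic
data design, and the numerical choices, in enough detail that results
can be interpreted and reproduced without reading the source.

## Models

**Homoscedastic animal model (M1).**  For a vector of scores y with
contemporary-group (CG) class effects and a linear age covariate in X
and a per-animal additive genetic effect a,

    y = X b + Z a + e,  a ~ N(0, A sigma2_a),  e ~ N(0, W^-1 sigma2_e),

with A the pedigree numerator relationship matrix and W optional
per-record weights.  Heritability is h2 = sigma2_a / (sigma2_a +
sigma2_e).

**Double hierarchical GLM (M2).**  The residual variance gets its own
linear mixed model on the log scale.  Writing s2_i for the current
predicted residual variance of record i and h_i for the mean-part
hat-matrix diagonal (leverage), the working response is

    psi_i = log s2_i + (e_i^2/(1 - h_i) - s2_i) / s2_i,

which is the first-order expansion of log e_i^2 around log s2_i; its
conditional variance is approximately 2/(1 - h_i) because a squared
Gaussian residual has relative variance 2.  The trait and psi are fitted
jointly as a bivariate animal model with residual weights W =
diag(1/s2_i) and W_v = diag((1-h_i)/2), correlated genetic effects
(a, a_v) ~ N(0, G (x) A), and two scaling residual variances expected to
converge near 1.  After each bivariate fit, s2_i is refreshed from the
variance-part linear predictor exp(x_i b_v + a_v,i) (random effect
included), residuals and leverages are recomputed, and the cycle repeats
until the five components change by less than the tolerance (default
1e-6 relative, with an absolute floor of 1e-6 for near-zero components).

**Exponential variance model (M3).**  The generative model

    y_i = x_i b + a_i + exp(0.5 (x_i b* + a*_i)) eps_i,  eps_i ~ N(0,1),
    (a, a*) ~ N(0, G (x) A),  G = [[s2_a, rho s_a s_a*], [., s2_a*]],

is fitted by MCMC: flat priors on b and b*, inverse-Wishart(nu = 4,
V = 0.01 I) on G.  Under this model heritability varies with the
systematic variance-part level:
h2_i = s2_a / (s2_a + exp(x_i b* + s2_a*/2)), summarised per draw and
then averaged (never plug-in).  The mean/variance genetic correlation
rho is itself the r_mv parameter.

**Uniformity parameters.**  The variance-part genetic variance on the
log scale converts to the additive (trait-units^4) scale by the exact
lognormal identity s2_av,add = m^2 (exp(s2_av) - 1), with m the mean
residual variance (first-order form m^2 s2_av available as a switch;
they agree within 1% below s2_av ~ 0.02).  Then
hv2 = s2_av,add / (2 sigma_p^4 + 3 s2_av,add) with sigma_p^2 = s2_a + m,
GCV_E = sqrt(s2_av,add)/m (DHGLM convention) or sqrt(exp(s2_a*) - 1)
(exponential-model convention), and r_mv = cov(a, a_v)/sqrt(s2_a s2_av),
clipped to [-1, 1] with a warning.  Standard errors for hv2 follow the
delta method over (s2_av,add, sigma_p^2).

## Estimation machinery

All three models run on one sparse backbone.  The mixed-model equations
are solved by eliminating the small fixed-effect block (CG classes +
age; the age column is dense) through a Schur complement, so only the
random-effect block S — pedigree-A-inverse sparsity plus a diagonal —
is factorised sparsely (SuperLU, minimum-degree ordering).  The REML
log-likelihood is exact:

    -2 l_R = log|R| + log|Sigma_u| + log|S| + log|Schur| + y'Py + const.

Exact hat-matrix diagonals and conditional-covariance traces come from
an LDL' factorisation with a Takahashi selected inverse (numba), whose
symbolic analysis is done once per sparsity pattern and reused; for the
bivariate system the analysis uses a pattern-complete template so the
same factor serves every G.  Leverages are exact at every problem size;
no stochastic estimator is needed.

* M1 maximises the REML likelihood by Nelder-Mead on log variances
  (a classical dense EM-REML path with a monotone likelihood trace is
  available for small systems as `method="em"`); standard errors come
  from the finite-difference observed information, and the h2 SE from
  the delta method.
* M2's inner bivariate fit maximises the working REML likelihood with
  *analytic* gradients from the score identities
  dl/dG = -1/2 (q G^-1 - G^-1 M G^-1), where M = U'A^-1 U + Tr and
  Tr_jk = tr(A^-1 Cov(u_j, u_k)) is evaluated exactly via the selected
  inverse plus the fixed-effect Schur correction; gradients are verified
  against finite differences in the test suite.  The optimiser is
  block-coordinate L-BFGS-B: one pass over the mean-part parameters
  (log s2_a, log scale_e) and one over the variance-part parameters
  (log s2_av, atanh r, log scale_ev).  The variance-part block sits on a
  long flat likelihood ridge when s2_av is weakly identified; a joint
  5-parameter search can ride that ridge to near-singular G (|r| -> 1),
  whose exploding prior precision then collapses the whole fit — the
  block scheme plus a parameter box (variances <= e, |atanh r| <= 2)
  removes this failure mode while leaving the well-identified mean part
  at its conditional optimum.  Plain EM was rejected because it moves
  the weakly identified component only at the information rate (it
  returns its initialisation); an unblocked quasi-Newton search was
  rejected for the ridge instability above.
* M3's sampler (numba kernel) updates per sweep: fixed effects b by
  single-site Gibbs; breeding values a by single-site Gibbs using the
  sparse A-inverse rows; b* by adaptive random-walk Metropolis per
  coefficient (target acceptance ~0.4, adaptation frozen at the end of
  burn-in); a* by a Laplace-style independence Metropolis step whose
  Gaussian proposal combines the prior conditional with the expected
  likelihood curvature (1/2 per record) — acceptance is ~0.97+ in the
  small-s2_a* regime, better than family-blocked random walks; and G by
  its inverse-Wishart full conditional.  Posterior summaries use
  effective sample sizes from initial-positive-sequence autocorrelation;
  the Geweke diagnostic compares the first 10% and last 50% segment
  means with batch-means spectral variances (25 batches per segment) at
  the 5% level, and is calibrated on iid chains by simulation in the
  test suite.  Constant chains are flagged degenerate, not passed.

## Synthetic data

The generator emulates a breed-association foot-scoring study.  Its
population structure follows the published data structure exactly: one
recorded cohort whose parents carry no records (the published counts —
45,667 records, 3,069 sires, 32,072 dams, 80,808 pedigree animals —
are consistent only with disjoint recorded/parent sets), mean 16.8
progeny per sire and ~1.4 per dam, male fraction 0.22, childless
founders pruned, pedigree/record ratio ~1.77.  This matters beyond
cosmetics: when parents and offspring are both recorded, their BLUP
residuals are correlated along the pedigree and the DHGLM working
response misreads that correlation as variance-part genetic signal.

Records get contemporary groups of ~250 (20 CGs at n = 5000), ages
uniform on 330-730 days (inside the 321-7796 d editing window), mean
5.5, CG effect SD 0.35 (giving total phenotypic SD ~0.7 at the default
variance components), age slope 5e-4 score/day, and CG effects on the
log residual variance with SD sqrt(0.049).  Phenotypes are drawn from
the exponential variance model; presets carry published
variance-component truths for the foot-angle and claw-set traits
(fa_m3: s2_a = 0.05, s2_a* = 4.35e-4, rho = 0.35, base log var
log 0.30; cs_m3: 0.02 / 7.28e-4 / 0.33 / log 0.24; fa_m2: 0.04 /
7.85e-4 / 0.52 / log 0.31; homoscedastic: s2_a* = 0).  The baseline
log-variances are chosen so the expected residual variance matches the
homoscedastic fit of the corresponding trait.

What the generator does **not** emulate: the positive skewness (~0.78)
and kurtosis of real score distributions (the generative model is
Gaussian; integer discretisation with clamping is available as an
extension and preserves ranking with Spearman r > 0.9, but does not
create skew); repeated records; herd/diet coding behind CG formation;
genotype-by-environment structure.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to score coarsening or non-normality.

## Identifiability at benchmark sizes

With a single record per animal, information about s2_a* comes from
relationship-weighted contrasts of log squared residuals, whose
intrinsic noise variance is ~2 per record.  A Fisher-information
calculation for the half-sib design (families of ~17) gives
SE(s2_a*) ~ 3e-2 at n = 5,000 — roughly 70 times the fa_m3 generative
value 4.35e-4 — and SE of the mean/variance genetic covariance ~4.5e-3
against a signal of 1.6e-3.  The same arithmetic at n = 45,667 still
gives SE(s2_a*) ~ 1e-2.  Consequently:

* the mean-part variance s2_a (and h2) is well identified and is
  recovered accurately by all three models;
* s2_a* and rho are *not* identified at these sizes.  The M3 posterior
  for s2_a* is dominated by the inverse-Wishart prior (marginal prior
  mean V/(nu - p - 1) = 0.01), and the posterior mean of rho shrinks
  toward the prior's centre of 0; the DHGLM point estimate of s2_av
  scatters over [0, ~3e-2] with its correlation pinned at a boundary.
  The package reports these quantities exactly as computed, with
  posterior SDs and standard errors that make the lack of information
  visible.  Recovery claims for them should be read accordingly.

## Problem sizes used by scripts/acceptance.py

The acceptance script simulates n = 5,000 recorded animals (pedigree
~8,900) per replicate.  The exponential model runs 3 replicate chains of
35,000 iterations (7,000 burn-in, thinning 10); the DHGLM runs 6
replicates with up to 15 outer cycles.  These sizes keep the full script
under ~15 minutes on one CPU while leaving the well-identified targets'
Monte-Carlo error well below their acceptance tolerances.

## Degenerate inputs and numerical choices

Pedigree cycles and conflicting duplicate rows are hard errors; phantom
parents become unknown-parent founders with inbreeding 0.  A-inverse
uses inbreeding-adjusted Henderson rules with Meuwissen-Luo inbreeding
coefficients; log|A| is the sum of log Mendelian-sampling variances.
Variance components are floored at ~1e-8 of the phenotypic scale during
optimisation; leverages are clipped below 1 - 1e-10 (a leverage of 1
makes the psi correction infinite and raises); the variance-part linear
predictor is clipped to +-30 on the log scale before exponentiation.
Cleaning filters iterate to a fixed point so the record set is
independent of rule order, and every dropped record is attributed to
exactly one rule with conserved counts.
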