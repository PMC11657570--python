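# Methods

## Model

`ziclust` estimates two-level (respondent-in-city) count regression models
for survey responses with many zeros. The response y_ij (cigarettes per
day for respondent j in city i) follows one of three count families on a
log-rate link, optionally mixed with a structural-zero component on a
logit link:

- **Poisson** — mean μ = e^η, variance μ.
- **Negative binomial (NB2)** — mean μ = e^η, dispersion r, variance
  μ + μ²/r. The classical (r, p) parameterization with mean r(1−p)/p is
  available through `nb_mu_from_rp`; fitting uses the mean/dispersion
  form, the standard choice for regression on a log-mean link.
- **Conway–Maxwell–Poisson (CMP)** — pmf λ^y/(y!)^ν / Z(λ, ν), rate
  λ = e^η, dispersion ν ≥ 0 (ν < 1 over-dispersed, ν = 1 Poisson, ν > 1
  under-dispersed). The rate parameterization is exposed directly;
  a mean-parameterized CMP is a possible extension but not the default,
  since the effect estimates to be compared against are defined on the
  log-λ scale.

The zero-inflated mixture puts probability φ on a structural zero (a
non-smoker), so P(Y=0) = φ + (1−φ)f(0) and P(Y=y) = (1−φ)f(y) otherwise.
City heterogeneity enters as independent normal random intercepts: u_i
(SD σ_u) in the count part, and — for zero-inflated models only — w_i
(SD σ_w) in the zero part. This yields free-parameter counts of
p_count + 1 (+1 dispersion for NB/CMP) for the plain models and
p_count + p_zero + 2 (+1 dispersion) for the zero-inflated ones; with the
full survey coding of 24 fixed effects per part that is 25/26/26/50/51/51
across TL-P/NB/CMP/ZIP/ZINB/ZICMP.

## CMP normalizing constant

Z(λ, ν) has no closed form. It is computed as a truncated series in log
space: blocks of terms t_i = i·log λ − ν·log i! feed a streaming,
max-rescaled accumulation of Z and, from the same exponentiation, the
moments E[Y], Var[Y] and E[log Y!] needed for gradients and curvature.
Truncation stops once the terms are decreasing *and* the current term is
below `rel_tol` (default 1e-12) times the running sum; because the terms
peak at i ≈ λ^{1/ν} and decay super-geometrically afterwards, the
neglected tail is then negligible. A hard cap of 1e6 terms converts a
(near-)divergent series into an explicit `CMPDivergenceError`; the peak
location is checked analytically first so hopeless cases fail instantly.
ν = 0 is allowed only with λ < 1 (geometric case). Sampling inverts the
CDF on a truncated support (tail < 1e-12), which is exact up to
truncation and reproducible from a seed.

During model fitting the family evaluates these statistics for tens of
thousands of η values that span a narrow range. Arrays of ≥ 2048 entries
are therefore evaluated on a dense log-λ grid (spacing 2e-3) and cubic-
spline interpolated; all four statistics are smooth in log λ, and the
interpolation error (~1e-9 on log Z) is orders of magnitude below the
quadrature error of the surrounding marginal-likelihood evaluation. Small
arrays and all public `cmp_*` functions always use direct summation.

## Marginal likelihood and estimation

Each city's random intercepts are integrated out by **adaptive
Gauss–Hermite quadrature**: a damped Newton iteration (analytic gradient
and Hessian of the penalized per-cluster objective, vectorized over
clusters and warm-started between likelihood evaluations) locates the
posterior mode of (w_i, u_i); the product Gauss–Hermite rule (default
K = 15 nodes per dimension) is then centred at the mode and scaled by the
Cholesky factor of the inverse curvature. Independence of w and u makes
the two-dimensional rule a product rule; non-zero-inflated models
integrate over u only, and K = 1 recovers the Laplace approximation.
Against dense-grid (20,001-point trapezoid) integration the quadrature
agrees to ~1e-10 on small clusters, and adaptivity keeps the largest
cluster (235 respondents, sharply peaked integrand) as accurate as the
smallest (5).

Maximization uses L-BFGS-B over (β, α, log dispersion, log σ_u, log σ_w)
with analytic gradients: the gradient of the quadrature approximation is
the posterior-node-weighted sum of observation scores plus the prior
terms for the variance components (node positions treated as fixed — the
induced error is of the order of the quadrature error itself, and the
gradient is verified against finite differences in the tests). Starting
values come in stages: a fixed-effects-only fit ignoring clustering, then
the random-effect variances enter at 0.1. Optional jittered multi-starts
are tie-broken by highest log-likelihood, then smallest gradient norm.
Parameter regions where the CMP series cannot be represented under the
term cap return a smooth quadratic penalty pulling back toward the start,
and the optimizer restarts once from the best evaluated point if it
stalls inside such a region. Convergence requires a finite optimum and a
gradient max-norm below 1e-4 relative to |LL|, alongside L-BFGS-B's
relative-change criterion (ftol 1e-10).

Standard errors are square roots of the diagonal of the inverse observed
information, obtained by central finite differences of the analytic score
at the optimum. Variance components may legitimately collapse to ~0 (the
boundary); the information matrix is then singular, SEs are computed from
a pseudo-inverse, and a warning marks them unreliable — the fit is
reported at the boundary rather than silently refitted without the
random effect. Separation in the zero part (a covariate level with no
smokers) surfaces the same way: a boundary-sized estimate with an
unreliable SE and a warning.

## Model comparison and effect tables

D = −2LL, AIC = −2LL + 2P, BIC = −2LL + P·ln(n) with n the number of
observations (not clusters), and MSE = mean (y − ŷ)² where ŷ is by
default the *conditional* fitted mean, plugging in the empirical-Bayes
modes of the random effects (the conventional choice for multilevel
fits; a `conditional=False` switch gives marginal means instead). Models
are ranked on every index; the overall winner is chosen by AIC with a
BIC tiebreak, and disagreements between indices are flagged rather than
hidden. Effect tables exponentiate the coefficients (OR for the zero
part, RR for the count part) with reference levels fixed at exactly 1.

## Synthetic survey generator

The generator emulates the motivating survey's published structure:

- **Clusters** — the 29 city sizes (5–235; total 1,973).
- **Covariates** — twelve categoricals sampled independently from the
  published per-level counts (counts, not the printed percentages, which
  contain typos). Independence across covariates ignores real-world
  association (e.g. "housewife" implies female); an optional joint
  sex × occupation table is accepted where that matters.
- **Response** — the two-level zero-inflated model itself, by default the
  CMP family with ν = 0.38 and the published effect estimates as true
  coefficients. The part intercepts are not published; they are fixed at
  α₀ = 3.55 and β₀ = −0.22, chosen once so that the simulated population
  reproduces the survey's ~90% non-smoking rate (an 88–92% envelope
  across seeds) with a mean daily count near 1. Random-intercept SDs
  default to σ_w = σ_u = 0.2 — deliberately away from the near-zero
  boundary values of the published fit — so that recovery tests exercise
  the integration machinery rather than a degenerate special case.
  The default seed is 20230529 and all randomness flows from one
  generator.

What passing tests on these data do **not** show: the generator has no
covariate correlations, no informative cluster-covariate structure
(city-level covariate differences), no missing data, and a heavier CMP
tail than plausible for real consumption counts (simulated maxima can
exceed 100 cigarettes/day). Recovery and preference results therefore
validate the estimation machinery under the assumed model, not the
field realism of the survey.

## Numerical choices and problem sizes

- Logistic and mixture terms evaluated via log-sum-exp throughout; rates
  for Poisson/NB capped at e^30 during optimization trial steps only.
- Quadrature default K = 15; the Monte-Carlo studies in the test-suite
  use K = 5–7 and a reduced covariate set (sex only), where K-refinement
  changes the log-likelihood by far less than 1e-6 — chosen as the
  package's own balance between resolution and the size of the studies
  (100 recovery replicates per family at n = 1,973).
- Smoking severity classes: 0 none, 1–5 light, 6–10 moderate, >10 heavy;
  a "smoker" is any respondent with y > 0 at interview.
- Bivariate screening tests (chi-square on smoker status; Mann–Whitney/
  Kruskal–Wallis on counts) use scipy defaults (continuity correction on
  2×2 tables, tie-corrected large-sample p-values) and are reporting
  conveniences only.

## Known limitations

- The plain TL-CMP model on heavily over-dispersed, zero-heavy data
  drives ν toward ~0.03, where representing Z would need more than the
  1e6-term cap once quadrature spreads λ above 1; such fits stop at that
  boundary and are honestly flagged `converged = False`. (Reference
  implementations report the same fragility for CMP on some datasets.)
  The zero-inflated CMP, which is the scientifically relevant model here,
  does not suffer from this: its ν̂ stays in a comfortable range.
- Wald SEs for variance components at the boundary are unreliable by
  construction (see above); no profile-likelihood or mixture-null
  correction is attempted.
- No hurdle models, random slopes, crossed effects, >2 levels, or
  Bayesian estimation.
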