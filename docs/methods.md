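# Methods

This document records the statistical model, the estimation algorithm, the
default parameter choices and their rationale, and the known limitations of
`sociovar`. It makes no empirical claims beyond what the package's own test
suite and acceptance script compute.

## 1. Model

Let `y_i` be the standardized score of individual `k[i]` on indicator `j[i]`
at assessment wave `t[i]`. The base model (Model 1) is a linear mixed model
with three *crossed* random intercepts:

```
y_i = x_i' beta + gamma_k[i] + alpha_{j[i], k[i]} + delta_{t[i], k[i]} + eps_i

gamma ~ N(0, s2_trait)        one intercept per individual
alpha ~ N(0, s2_indicator)    one per individual x indicator cell
delta ~ N(0, s2_state)        one per individual x wave cell
eps   ~ N(0, s2_resid)        per observation
```

All random terms are mutually independent and independent of `eps`. The
fixed effects `x_i` are intercept, age at observation, gender (0 = women,
1 = men) and assessment wave (years since the first wave). Each component's
"Var %" is its percentage of the sum of *all* model variances.

The genotype model (Model 2) adds a genotype covariate `g_k` (the 0–4
cumulative risk score, or a single SNP's 0/1 risk flag) as a fixed effect and
three variance-moderation ("GxE") terms. A moderation term at level `l` adds
random effects `xi_l` whose design-matrix entries are `g_k` instead of 1, so
individuals with `g_k = 0` receive none of that variance and carriers receive
`g_k^2 * s2_xi_l` extra variance at that level. A non-trivial `s2_xi` is an
indirect test of GxE interaction: the genotype changes the *magnitude* of
trait, indicator or state variance rather than the mean.

### Indicators and scoring

Five indicators are built in: NEO-FFI Extraversion (12 items, administered
only at the last two waves), TCI RD1 Sentimentality (10 items), TCI RD3
Social Attachment (8 items), TCI RD4 Dependence (6 items, all reverse-keyed:
a raw response `r` on the 1–5 scale contributes `6 - r`), and EAS
Sociability (5 items). A scale score is the mean of answered items provided
at least 75 % of items are answered (inclusive); otherwise the score is
missing. Scores are standardized against the distribution (mean and ddof-1
SD) of a fixed reference wave — default 2007, the wave at which all five
indicators were administered — so that scores are comparable across
instruments and waves.

### Genotype coding

Risk groups: rs1042778 TT; rs2254298 GG; rs53576 AA or AG; rs3796863 CC.
Allele order within a genotype string is ignored. The cumulative risk score
sums the four 0/1 flags and is missing if any flag is missing (individuals
with an incomplete panel are excluded from genotype models; the run log
records the count).

## 2. Estimation

### Profiled REML/ML criterion

Estimation follows the penalized-least-squares formulation standard for
sparse mixed-model software. Stack the random-effect design matrices into
`Z = [Z_1 | ... | Z_B]` and parameterize each block by the ratio
`theta_b = sd_b / sd_resid`. With `D = diag(theta)` expanded per column,
solve the extended normal equations through the sparse Cholesky-like
factorization of

```
M(theta) = D Z' Z D + I
```

using SuperLU (`scipy.sparse.linalg.splu` with `permc_spec="MMD_AT_PLUS_A"`,
`diag_pivot_thresh=0`, symmetric mode), which yields `log det M` from the
diagonal of U. The fixed effects are obtained from the Schur complement
`S = X'X - (DZ'X)' M^{-1} (DZ'X)`, the residual sum of squares from
`r2 = y'y - c_zy' b_hat - (X'y)' beta_hat`, and the residual variance is
profiled out: `sigma2_hat = r2 / nu` with `nu = n - p` for REML and `nu = n`
for ML. The objective is

```
-2 LL(theta) = log det M + [log det S, REML only] + nu * (1 + log(2 pi sigma2_hat))
```

This is verified in the test suite against a brute-force dense oracle that
builds the explicit marginal covariance `V = sum theta_b^2 Z_b Z_b' + I`
(agreement to 1e-8 at small n, and the optimum matches a dense-path polish).

### Optimization

The criterion is minimized over `eta = log theta` with L-BFGS-B
(bounds [-13, 8], finite-difference step 1e-5 chosen to exceed the
criterion's round-off noise at n_obs ~ 3e4) from up to three seeded starting
points, followed unconditionally by a Nelder–Mead polish
(`xatol=1e-9`, `fatol=1e-11`). Components with `theta < exp(-12)` are
reported as exact zeros with a boundary flag. Non-convergence of all
restarts raises `ConvergenceError`.

### Inference

- **Fixed effects:** `Var(beta_hat) = sigma2_hat S^{-1}`; p-values use the
  normal approximation (with tens of thousands of observations and hundreds
  of groups the t/normal distinction is negligible; see Limitations).
- **Variance-component intervals:** profile likelihood by default — the
  interval is the set of component values whose profiled deviance (nuisance
  parameters re-optimized) lies within the chi-square(1) quantile of the
  fitted deviance; endpoints are located by Brent root-finding. A parametric
  bootstrap (`method="boot"`) is available as a cross-check. Coverage of the
  profile intervals is verified at 0.95 ± 0.03 over 300 replicates in the
  acceptance suite.
- **Model comparison:** AIC = -2 LL + 2 (p + B + 1), defined only for ML
  fits on identical response vectors; `compare_aic` enforces both.
- **Per-indicator association:** for one SNP and one indicator, an
  individual-random-intercept model with age, gender, wave and a sum-to-zero
  (+1/-1) genotype contrast; the contrast is tested with a Wald
  F(1, n_obs - rank(X)) statistic, and the two genotype groups' deviations
  (which sum to zero) are reported with standard errors. Small genotype
  groups trigger a warning. Type-I error is verified at 0.05 ± 0.02 over
  1000 null replicates.

## 3. Synthetic cohorts

`simulate_cohort` draws from exactly the model above under an accelerated
longitudinal design: six birth cohorts (1962–1977, 3-year spacing) assessed
at four waves (1997, 2001, 2007, 2012), five indicators with NEO-FFI-E
restricted to the last two waves, so age at observation spans 20–50 while no
individual is followed for more than 15 years. `design_occupancy` tabulates
the resulting wave-by-age-band coverage. Genotypes are drawn per SNP under
Hardy–Weinberg proportions calibrated so the marginal risk-group frequencies
match the configured values (defaults 0.154, 0.843, 0.664, 0.408 for
rs1042778 TT, rs53576 AA/AG, rs3796863 CC, rs2254298 GG respectively).

Default generating parameters (all overridable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_individuals` | 800 | recovers all components well within tolerance in ~1 s per fit |
| variance components | 0.212 / 0.387 / 0.048 / 0.298 | the package's reference decomposition (trait / indicator / state / residual) |
| `beta_intercept, beta_age, beta_gender, beta_wave` | 0.438, −0.007, −0.442, −0.001 | reference fixed effects on the standardized scale |
| `prop_women` | 0.59 | reference cohort composition |
| `missing_rate` | 0.0 | the design-driven absences (NEO-FFI-E at two waves only) are always present; extra completely-at-random dropout is opt-in |
| `genotype_missing_rate` | 0.0 | genotype availability differences are simulated explicitly when needed |
| `seed` | 0 | all draws flow from one `numpy` Generator; same seed, same bytes |

`gxe` entries `(covariate, term, xi_var)` inject genotype-moderated variance
at one level, enabling power and null-calibration studies for the indirect
GxE test.

## 4. Numerical choices

- Sparse CSR design blocks throughout; the per-iteration cost is one SuperLU
  factorization of `M(theta)` (dimension = total number of random effects,
  e.g. ~7,000 at n = 800) plus dense work on the p x p Schur complement.
- The optimizer works on `log theta` so the positivity constraint is
  implicit and boundary components are reachable (as `exp(-13)` ~ 2e-6).
- Collinear fixed-effect columns are detected by pivoted QR and dropped with
  a warning; listwise deletion of rows with missing response or covariates
  is logged with counts.
- Variance shares are rounded half-away-from-zero (so 22.5 prints as 23, not
  22 as under banker's rounding).
- Determinism: fits are deterministic given data, spec and seed; pipeline
  outputs are byte-identical across reruns with the same config.

## 5. Limitations

- Random effects are independent intercepts; correlated random effects,
  random slopes and non-Gaussian responses are out of scope.
- Fixed-effect p-values use the normal approximation rather than a
  Satterthwaite or Kenward–Roger correction; with few groups they will be
  anti-conservative. The per-indicator F test uses a simple residual ddf for
  the same reason.
- Profile intervals assume the usual chi-square(1) calibration, which is
  approximate for components near the zero boundary.
- The GxE moderation term scales variance by the *square* of the covariate;
  with a 0/1 risk flag this is a carrier/non-carrier variance contrast, but
  with the 0–4 score it imposes a quadratic dose shape by construction.
- The simulator draws genotypes independently across SNPs (no linkage
  disequilibrium) and generates missingness completely at random; neither
  matches every real cohort.
- Raw item generation is not simulated; `simulate_cohort` emits standardized
  scores directly. Item-level pipelines are exercised via `score` with
  user-provided item tables.
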