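# Methods

## The model

`darkcore` studies how well subsets of aversive personality trait scales
approximate the common core (D) of all aversive traits. The measurement
model is an orthogonal bifactor model over an N × p matrix of item
responses grouped into T trait scales: every item loads on a single general
factor (D) and on exactly one scale-specific factor, and all 1 + T factors
are mutually uncorrelated. The implied covariance is

    Sigma(theta) = Lambda Psi Lambda' + Theta,

with Lambda the p × (1+T) bifactor loading pattern, Psi the diagonal matrix
of factor variances and Theta the diagonal residual variances. Factors are
identified by marker variables: the loading of the first item overall is
fixed to 1 for the general factor, and the first item of each scale is fixed
to 1 for that scale's specific factor, leaving the factor variances free.
This gives (p−1) + (p−T) + p + (T+1) free parameters and
df = p(p+1)/2 − [(p−1) + (p−T) + p + (T+1)]; for the default configuration
(p = 151 items in 16 scales) df = 11,023.

Likert responses are treated as continuous in estimation. Parameters are
estimated by normal-theory maximum likelihood, minimizing

    F_ML = ln|Sigma| + tr(S Sigma^{-1}) − ln|S| − p

over the free parameters, where S is the biased (divide-by-N) sample
covariance. The test statistic is chi² = N · F_ML (an N−1 convention is
available via `FitOptions.chi2_n`). RMSEA is
sqrt(max(0, (chi² − df)/(df · N))) with a 90% CI obtained by inverting the
noncentral chi-square tail probabilities 0.95/0.05 at the observed
statistic; SRMR is the root mean square of correlation-metric residuals over
the p(p+1)/2 unique elements including the diagonal (both matrices
standardized by their own diagonals, so diagonal residuals are zero but
counted in the denominator).

## Optimization

The discrepancy is minimized with L-BFGS-B using the analytic gradient
(with G = Sigma⁻¹(Sigma − S)Sigma⁻¹: dF/dLambda = 2 G Lambda Psi,
dF/dPsi = diag(Lambda' G Lambda), dF/dTheta = diag(G)). Starting values come
from a one-factor principal-axis solution rescaled to the marker metric
(general loadings and general-factor variance), 0.3 for free specific
loadings, half the item variance for residuals and a quarter of the marker
item's variance for specific-factor variances.

Residual and factor variances are bounded below at 1e−4 times the relevant
item variance rather than being allowed to go negative; a solution at the
bound is flagged (`heywood=True`). Since Psi ≥ 0 and Theta > 0 keep
Sigma(theta) positive definite by construction, the objective is evaluable
everywhere in the feasible region, which matters when tens of thousands of
subset models are fit unsupervised. On failure the optimizer restarts from
multiplicatively jittered starting values (lognormal, sd 0.2, seeded), up to
`max_restarts = 5`, keeping the best solution; a fit that still fails is
returned with `converged=False` and excluded from summaries with a reported
count. Because the line search can stall at machine precision (`ftol =
1e−14`) with the projected gradient already negligible, a fit also counts as
converged when the maximum absolute gradient falls below `gtol_accept =
1e−5`; fitting an exact population covariance this way reaches F_ML ≈ 1e−12
with parameters recovered to ~1e−5.

## Factor scores and ECV

D scores use the regression (Thurstone) method,
F̂ = Psi Lambda' Sigmâ⁻¹ (x − x̄), with the model-implied covariance; they
are determinate, closed-form and reproducible. Scores are sign-aligned so
the sum of completely standardized general loadings is positive; reported
correlations between reduced and full D are therefore signed, not absolute
values. The explained common variance of scale t,

    ECV_t = Σ_i ℓ²_{g,i} / (Σ_i ℓ²_{g,i} + Σ_i ℓ²_{s,i}),

uses completely standardized loadings ℓ = λ√ψ / sd(item), so it is invariant
to the units of individual items. ECV measures a trait's D saturation.

## Subset pipeline

All subsets of k trait scales, k from `k_min` (2) to `k_max` (11), are
enumerated in lexicographic order; with 16 traits that is 63,002 subsets.
The full model is fit once and its D scores kept as the criterion. Each
subset's reduced bifactor model (general factor over the included items,
specific factors for included scales only) is refit from scratch and its D
scores correlated (Pearson) with the criterion. Per-subset engine seeds are
derived from (global seed, CRC32 of the sorted trait names), so results are
identical under any worker count and execution order.

Summaries report, per subset size: the number of combinations, the median
and 1st/5th/10th percentiles of r (linear interpolation between order
statistics — the percentile definition is recorded in the summary metadata);
per included trait: the conditional distribution of r; the composition of
the extreme tails (ties at the cutoff all included; with `tail=1` each
trait's inclusion frequency is k/T, a useful self-check); and named-set
comparisons (the Dark Triad {Machiavellianism, SD3-Narcissism, Psychopathy},
the Dark Tetrad adding Sadism, and the NARQ variants that swap the
narcissism measure) against the median of all same-size subsets and the
medians of same-size subsets containing each member. A stopping diagnostic
reports the gain in the per-k median from k to k+1, which justifies a k_max
once it drops below a negligible threshold (.005 in the original design).

## Synthetic data generator

The generator emulates the study's data situation: 16 scales with item
counts 13, 12, 9, 6, 14, 7, 9, 8, 9, 6, 8, 9, 10, 4, 17, 10 (p = 151),
five-point Likert items, about 1,700 respondents, and heterogeneous D
saturation. Latent item values are built from independent standard-normal
factor scores and residuals on the standardized metric and cut at four
strictly increasing thresholds per item.

The published loading matrix is available only in the study's online
supplement, so the default population is stylized rather than a
reproduction: loadings vary linearly across each scale's items within
per-scale ranges chosen to span the documented saturation gradient —
Frustralia-, Machiavellianism- and Crudelia-like scales load ~0.60–0.75 on
the general factor (specific ~0.20–0.35), SD3-Narcissism-, Entitlement- and
Greed-like scales ~0.25–0.40 (specific ~0.55–0.70), the rest in between.
Thresholds are the symmetric base (−1.8, −0.6, 0.6, 1.8) shifted rightward
by a per-scale offset between 0.15 and 1.3, placing expected item means
between ≈1.96 and ≈2.88; the Sadism-like scale's offset of 2.1 produces the
floor effect (expected mean ≈1.45 against the documented 1.44) while its
latent saturation stays moderately high — the attenuation is purely a
censoring artifact, as in the original data. A deterministic retry (derived
sub-seed) guards against constant columns at small n; otherwise the same
(model, n, seed) yields bitwise-identical data.

What the generator does not emulate: careless or inattentive responding,
missing data, item-level idiosyncrasies (cross-loadings, correlated
residuals), non-normal latent distributions, and sampling from a real panel.
Passing tests therefore demonstrate that the pipeline recovers known
structure under the model's own assumptions, not that the published
point estimates would be reproduced on the OSF raw data.

## Problem sizes used in tests and the acceptance script

Exact identities (combinatorics, df, RMSEA from the published statistic) run
at full scale. Parameter recovery fits the complete 151-item model twice:
once on the exact population covariance and once on continuous data at
n = 5,000 (each fit takes a few seconds). End-to-end subset enumeration runs
on a scaled-down gradient population — 8 scales × 4 items, n = 800 Likert,
k ∈ [2, 5], 210 refits — where the lowest- and highest-saturation traits are
planted by construction (general loadings 0.20 → 0.75 across scales). These
sizes are the package's default study conditions for its own verification;
the full 63,002-subset run on 151 items is available through the CLI for
users with the patience for it.

## Known limitations

- No standard errors or robust corrections; no mean structure; no
  missing-data ML; no polychoric correlations (items are treated as
  continuous, as in the original analysis).
- The default population's loadings are stylized; only orderings and ranges
  are contractual, not individual values.
- Regression factor scores are one of several defensible scoring methods;
  Bartlett scores are not implemented.
- Heywood cases are prevented by bounding rather than diagnosed; severely
  misspecified models will show bound-hitting (`heywood=True`) rather than
  negative variances.
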