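# Methods

## Model and sampler

`priorscope` fits the normal linear regression
y = β₀ + Xβ + ε, ε ~ N(0, σ²I), with independent normal priors
N(μ₀ⱼ, v₀ⱼ) on the intercept and each coefficient and an inverse-gamma
prior IG(a₀, b₀) on σ². All normal priors are parameterized as
(mean, **variance**); configuration files and APIs never accept an SD or a
precision, because mixing those conventions is the single most common way a
prior sensitivity analysis silently goes wrong.

The Gibbs sampler alternates two exact conditional draws. The coefficient
vector (intercept included) is drawn **jointly** from its multivariate
normal full conditional — covariance (V₀⁻¹ + XᵀX/σ²)⁻¹ — rather than one
coordinate at a time. For this conditionally conjugate model the block
update leaves almost no autocorrelation in the chain, which is what makes
an ESS above 1,000 attainable from only 2,500 kept draws. σ² is then drawn
from IG(a₀ + n/2, b₀ + RSS/2).

Defaults, all overridable:

| setting | default | rationale |
| --- | --- | --- |
| iterations | 5,000 | standard single-chain run length for this model class |
| burn-in | half of the iterations | "first half discarded" convention |
| chains | 1 | single-chain workflow; R-hat uses split halves |
| intercept prior | N(0, 10¹⁰) | effectively flat on any realistic outcome scale |
| σ² prior | IG(−1, 0), improper | flat on σ²; the default of the Mplus-style Bayes estimator this package mirrors. IG(0.001, 0.001) is available as a proper alternative; improper settings must be acknowledged with `proper_flag=False` |
| HPD level | 0.90 | conventional reporting level for this workflow |
| convergence thresholds | R-hat < 1.01, ESS > 1,000 | strict single-chain criteria |

Numerical details: σ² is initialised at the sample variance of the outcome
(deterministic given the data). All raw randomness — the standard normals
for the coefficient draw and the gamma variates for the σ² conditional
(whose shape a₀ + n/2 is iteration-constant) — is pre-generated from a
per-chain seed. Batched simulation replications therefore produce chains
bit-identical to standalone runs with the same seeds, and cell aggregates
do not depend on execution order or batch composition. Contractions inside
the sampler use shape-stable operation orders for the same reason. An
improper conditional (a₀ + n/2 ≤ 0, or a non-positive scale) raises an
estimation error naming the offending hyperparameters.

## Summaries and diagnostics

**HPD interval.** Shortest contiguous window containing ⌈level·N⌉ sorted
draws; width ties break toward the lowest lower bound (the first minimal
window in sorted order). Degenerate samples yield a zero-width interval.

**Split R-hat.** Classic Gelman–Rubin PSRF: a single chain is split into
halves (the middle element is dropped at odd lengths); with m segments of
length L, R̂ = √(((L−1)/L·W + B/L)/W). The rank-normalized variant is
deliberately not used: the 1.01 single-chain criterion this package targets
is defined for the classic statistic. Constant chains raise a
degenerate-chain error.

**ESS.** N/(1 + 2Σρ̂ₖ) with the autocorrelation sum truncated by Geyer's
initial-monotone-positive-pair rule (autocovariances via FFT). Antithetic
chains can push the raw estimate above N; the raw value is reported, but
the convergence flag caps it at N — the threshold is a floor on
information, not a mixing score.

**Geweke z.** Difference of head (first 10%) and tail (last 50%) window
means over the square root of the summed variance-of-mean estimates, each
window's long-run variance estimated by a Bartlett-tapered spectral density
at zero with lags truncated at 4% of the window length.

The per-parameter convergence report never raises on a failed diagnostic:
it records NaN with a note and flags the parameter as not converged, since
in a sensitivity analysis non-convergence under some prior is itself a
finding.

## Sensitivity engine

A plan holds the original prior set and named alternatives; each
single-parameter alternative replaces exactly one prior, a combined
alternative replaces several at once, and the original is never mutated.
Every analysis gets a label-derived seed (base seed + CRC32 of the label,
mod 2³¹), so adding or reordering alternatives never changes existing
results. Every analysis reports **all** parameters — changing one prior can
legitimately move other posteriors — plus a convergence report; comparisons
give the percent deviation of each posterior mean from the original
(signed, with the signed original mean as denominator, so a downward shift
of a positive effect is negative; an original mean within 1e-8 of zero
yields an undefined-deviation NaN rather than an error), whether zero lies
in the closed HPD interval, and whether that conclusion changed. Posterior
densities are Gaussian KDEs with Silverman bandwidth on a 512-point grid
spanning the sample range ± 3 bandwidths.

## Simulation engine

The study population is a two-predictor regression: standard-normal
predictors linked by a correlation ρ, intercept 1, residual variance 0.5,
coefficients 1.0 and 0.5. Eleven coefficient-prior conditions are built in:
five informative (variance 0.05) and five weakly informative (variance 0.1)
with means at ¼×, ½×, 1×, 2× and 3× the true values, plus a diffuse
N(0, 10¹⁰) condition. Intercept and σ² keep the module defaults in every
condition. Each replication generates a fresh dataset (seed = cell base
seed + replication index; data and sampler use independently spawned
streams), fits the default 5,000-iteration chain, and records the posterior
mean as the point estimate (the posterior median is selectable). Cells
aggregate relative percent bias, MSE, the Monte-Carlo SE of the bias
estimate, and a convergence-failure count; a cell errors out only if more
than 5% of replications are unusable. Rendered tables flag |bias| > 10%.

**The predictor correlation ρ is a required input with no default in study
mode.** Shifted-prior cells at small n are sensitive to it, so it is a
declared design choice, always logged. The reproduction suite fixes
ρ = 0.3 (a moderate, realistic correlation) for its quantitative targets,
which are restricted to the accurate-prior and diffuse-prior cells — in
those cells the posterior mean is essentially unbiased for any moderate ρ,
because the prior either centres on the truth or carries no weight. Cells
with shifted priors are checked as ordering, monotonicity and sign
properties (at ρ = 0.5) rather than point targets, and those checks are
one-sided at 3 Monte-Carlo standard errors: with 200 replications several
small-shift cells have true biases below their own MC noise, so a raw sign
assert would test the noise, not the property.

Problem sizes in the reproduction suite — 500 replications for the
quantitative cells, 200 for the structural checks, 20 seeds for the ESS
floor — are the package's chosen trade-off between Monte-Carlo precision
and turnaround; all are configurable upward.

## Synthetic fixture

The `fixtures` module generates a "cynicism study" emulation: n = 100,
Bernoulli(0.5) `sex` (men coded 1), normal `lack_of_trust` (mean 3, SD 1),
and `cynicism` = 10 + 0·sex + 6·trust + N(0, 25). The true effects sit at
the centres of the original analysis priors (Trust N(6, 1), Sex N(0, 10)),
making those priors plausible by construction. This is an **emulation, not
a replication**: the empirical dataset behind the workflow this package
operationalizes is not publicly reconstructible, so its exact percent
deviations are not reproducible targets — only the directions of the
prior-induced shifts (Trust posterior down, intercept up under
zero-centred Trust alternatives) are asserted. Variable scales are
arbitrary, since the fictional study never states its instruments' ranges.

What passing tests on this fixture do show: the full pipeline (fit,
diagnostics, comparison, reporting) behaves correctly on data of the
stated size and structure. What they do not show: robustness to real-data
features the generator omits — non-normal residuals, heteroscedasticity,
measurement error, missing values (unsupported by design).

## Known limitations

* Identity link, single continuous outcome, complete cases only;
  non-conjugate and reference priors are out of scope.
* The improper default σ² prior requires n > p + 2; tiny samples should
  use a proper IG prior.
* Percent deviation and relative percent bias are undefined at (near-)zero
  denominators; the package reports NaN or directs to absolute bias rather
  than guessing.
* Single-chain R-hat on split halves can miss multimodality that multiple
  dispersed chains would catch; `chains > 1` is supported and recommended
  for suspect posteriors.
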