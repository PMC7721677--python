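# priorscope

Prior sensitivity analysis for Bayesian normal linear regression.

Applied Bayesian analyses stand or fall with their prior distributions, yet
most applied papers never examine how much the priors drive the reported
posteriors. `priorscope` is a toolkit for doing exactly that, aimed at
researchers in psychology, epidemiology and the wider social/health sciences
who fit small regression models with subjective or default priors. It
provides:

* a conjugate **Gibbs sampler** for normal linear regression,
* **convergence diagnostics** (split R-hat, effective sample size, Geweke z),
* **90% highest posterior density (HPD) intervals** and posterior summaries,
* a **sensitivity engine** that refits the model under named competing prior
  sets — one parameter at a time or combined — and compares posteriors via
  percent deviations and conclusion checks,
* a **Monte-Carlo simulation engine** measuring the bias that inaccurate
  priors induce, across sample sizes and prior informativeness.

## Model

For outcome $y_i$ and predictors $x_i \in \mathbb{R}^p$:

$$y_i = \beta_0 + x_i^\top \beta + \varepsilon_i, \qquad
  \varepsilon_i \sim \mathcal{N}(0, \sigma^2),$$

with independent priors $\beta_j \sim \mathcal{N}(\mu_{0j}, v_{0j})$
(**the second hyperparameter is a variance**, not an SD or precision) and
$\sigma^2 \sim \mathrm{IG}(a_0, b_0)$ (the improper flat $\mathrm{IG}(-1, 0)$
by default). The Gibbs sampler alternates exact conditional draws:

$$\beta \mid \sigma^2, y \sim \mathcal{N}\!\left(V_n\left(V_0^{-1}\mu_0 +
  \tfrac{X^\top y}{\sigma^2}\right),\; V_n\right), \quad
  V_n = \left(V_0^{-1} + \tfrac{X^\top X}{\sigma^2}\right)^{-1},$$

$$\sigma^2 \mid \beta, y \sim \mathrm{IG}\!\left(a_0 + \tfrac{n}{2},\;
  b_0 + \tfrac{\mathrm{RSS}(\beta)}{2}\right).$$

The coefficient vector is drawn as one block, so chains mix essentially like
independent draws. Defaults: 5,000 iterations, first half discarded as
burn-in, a single chain; convergence requires R-hat < 1.01 and ESS > 1,000.

The sensitivity comparison statistic is the percent deviation
$(\bar\theta_{\text{alt}} - \bar\theta_{\text{orig}})/\bar\theta_{\text{orig}}
\times 100$ between posterior means, alongside whether zero sits inside the
90% HPD interval (the substantive-conclusion check). The simulation engine
reports relative percent bias
$(\overline{\hat\theta} - \theta)/\theta \times 100$ and MSE of the
posterior-mean estimator over replications.

## Worked example

Generate the bundled synthetic "cynicism" study (n = 100; binary `sex`,
continuous `lack_of_trust`, continuous `cynicism`) and run a sensitivity
analysis of the Trust effect — original prior N(6, 1), alternatives
N(0, 100) (diffuse) and N(0, 5) (informative null):

```sh
priorscope fixture --out cyn.csv --seed 1
priorscope sensitivity --config sens.yaml
```

with `sens.yaml`:

```yaml
dataset: cyn.csv
outcome: cynicism
predictors: [sex, lack_of_trust]
priors:
  coefficients:
    sex: {mean: 0, variance: 10}
    lack_of_trust: {mean: 6, variance: 1}
chain: {seed: 1}
sensitivity:
  alternatives:
    - label: trust_diffuse
      parameter: lack_of_trust
      prior: {mean: 0, variance: 100}
    - label: trust_null
      parameter: lack_of_trust
      prior: {mean: 0, variance: 5}
output_dir: sens_out
```

Printed comparison (abridged):

```
   analysis      parameter  estimate      sd  hpd_lower hpd_upper original_estimate percent_deviation zero_in_hpd
   original  lack_of_trust  5.922996 0.438633   5.165615  6.628935          5.922996          0.000000       False
trust_diffuse lack_of_trust 5.870816 0.478314   5.033110  6.621589          5.922996         -0.880977       False
 trust_null  lack_of_trust  5.627990 0.476581   4.835292  6.391870          5.922996         -4.980693       False
 trust_null      intercept 10.440361 1.555441   7.932790 13.034221          9.555445          9.260848       False
```

Reading this: both alternative Trust priors pull the Trust posterior mean
down (−0.9% and −5.0%) and push the intercept up (the model re-allocates the
removed Trust contribution), but zero stays outside every 90% HPD interval —
the substantive conclusion that lack of trust predicts cynicism is robust to
these priors. `sens_out/` also receives a per-analysis convergence table,
density-grid and trace-series CSVs for plotting, a narrative skeleton, and a
manifest (config hash, seeds, versions) that makes the run reproducible
bit-for-bit.

The simulation engine runs the same way (`priorscope simulate --config ...`
with a `study:` section declaring sample sizes, prior conditions 1–11,
replications, and the population predictor correlation) and renders a
percent-bias (MSE) table with cells exceeding ±10% bias flagged.

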