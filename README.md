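# wholereport

Within-trial analysis and hierarchical Bayesian ensemble models for
**whole-report** visual working-memory tasks.

In a whole-report trial a participant sees N colored stimuli and, after a
delay, reports *all* of them — either in an order they choose or in a random
cued order.  Unlike single-report delayed estimation, this yields the joint
distribution of reports made within one trial, which is where assumptions of
working-memory models become testable: if stimuli were encoded and reported
independently, the signed circular distance between any two reports of the
same trial would be uniform on the circle.  This package provides, for both
task variants (a continuous 360-value color wheel and a discrete 8-button
response array):

- **Circular primitives** — wrapping to (−π, π], circular mean, mean
  resultant vector length (MRVL), von Mises density/sampling/ML fitting,
  plug-in KL divergence against a uniform reference, stimulus-grid snapping.
- **A task data model** with a documented long-format CSV dialect (one row
  per report; angles in degrees on disk, radians in memory).
- **Synthetic observers** — an independence null model and a
  similarity-grouping positive control — so the dependence analyses can be
  calibrated without human data.
- **Dependence analysis** — relative-distance distributions, 1000-fold
  bootstrapped KL divergence with size-matched uniform baselines (36 bins
  continuous / 8 discrete), MRVL summaries, one-way repeated-measures ANOVA.
- **Two ensemble encoders** with Gibbs-sampled posteriors:
  - the two-level **hierarchical Bayesian model (HBM)**:
    θᵢ | μₑ, κₑ ~ VM(μₑ, κₑ), with μₑ ~ U(−π, π], κₑ ~ U(0, 100), observed
    through xᵢ | θᵢ ~ VM(θᵢ, κ_obs); κ_obs is the only free parameter;
  - the **Bayesian finite mixture model (BFMM)**: K weighted von Mises
    components, π ~ Dirichlet(α,…,α), μₖ ~ U(−π, π],
    κₖ ~ Gamma(1, β), β ~ Gamma(1, 1), with the same observation channel.
- **Bias analysis** — whole-report simulation (observe → posterior → circular
  mode → snap to the response grid) and OLS regression of report error on the
  signed distance to the ensemble/component mean, restricted to (−π/2, π/2);
  a positive slope is attraction toward the mean.

## Worked example

Simulate the continuous task at set size 3 under the hierarchical encoder
with observation concentration κ_obs = 5, and measure the bias its reports
show toward the trial's mean color:

```python
from wholereport.pipeline import simulate_bias_experiment

sim, table, reg = simulate_bias_experiment(
    task="continuous", set_size=3, n_trials=100, model="hbm",
    kappa_obs=5.0, seed=7, draws=1000, tune=500)
print(reg.summary())
```

```
bias regression (all reports): slope=0.4821 intercept=0.0339 R^2=0.3007 p=1.24e-20 n=245
```

The slope says that a stimulus sitting 1 radian from the trial's mean color
is reported roughly 0.48 radians closer to that mean — the shrinkage the
hierarchical prior produces at this noise level (at κ_obs = 20 the same
experiment yields a slope near 0.08).  `n=245` counts the reports whose
distance to the mean falls in the linear domain (−π/2, π/2).

The model objects follow the statsmodels convention — a model built from
data whose `fit()` returns a results object:

```python
from wholereport import HierarchicalEnsembleModel, StimulusGrid

model = HierarchicalEnsembleModel([0.10, 0.25, -0.05], kappa_obs=5.0)
res = model.fit(draws=2000, tune=500, seed=0)
res.summary()                            # posterior means/sds/ESS per parameter
res.point_estimates(StimulusGrid(360))   # simulated reports, snapped to the wheel
```

A command-line interface covers the same pipeline end-to-end
(`wholereport simulate-task | simulate-model | analyze-dependence |
analyze-bias | fit-kappa | run | report`); `wholereport run --config cfg.json`
writes datasets, analysis tables and a checksummed manifest.

## Acceptance script

`scripts/acceptance.py` recomputes the eight simulation benchmark slopes from
scratch — the HBM at set size 3 and the BFMM (K = 6, α = 1) at set size 6,
each on both task variants at κ_obs ∈ {5, 20}, with 300 fresh trials per
condition and reduced MCMC:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints one line per condition (slope, R², in-domain n, runtime) and
writes the slopes to the JSON file; the whole run takes a few minutes on a
single CPU.
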