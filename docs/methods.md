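# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations.

## Conventions

All angles are radians on the half-open interval (−π, π]; `wrap_angle` is the
single wrapping boundary and every container stores wrapped values.  Response
grids place index 0 at angle 0 with spacing 2π/m (m = 360 continuous, m = 8
discrete), which makes the degree↔radian conversion for the 360-value task
exact.  Files store integer degrees; memory stores radians; the conversion
happens only at the I/O boundary.

## Task data model

A trial is indexed by report position: `presented[j]`, `reported[j]`,
`locations[j]` describe the j-th report (the probed display location, the
value shown there, the value reported).  Report errors are therefore computed
**per display location** — reported value minus the value presented at that
same location — with report order carried as metadata.  Discrete-task trials
never repeat a presented value; continuous-task trials sample the 360-value
grid with replacement, as in the source experiments.

## Dependence analysis

**Relative distance** between report positions i < j is the signed circular
difference (later minus earlier), preserving the attraction/avoidance
direction.  Distances are binned into equal arcs with one bin *centred at
zero* (edges at ±π/n_bins, …) so that near-zero distances share a single bin;
n_bins = 36 for the continuous task and 8 for the discrete task, where the
bin centres coincide with the response values.

**KL divergence** is the plug-in estimator Σ P log₂(P/Q) with 0·log 0 = 0 and
no pseudocounts (Q = 1/n_bins is strictly positive, so the estimate is always
finite and bounded by log₂ n_bins).  Each empirical estimate is a median over
1000 bootstrap replicates; resampling distances with replacement and binning
commute, so replicates are drawn directly as multinomials on the empirical
bin frequencies.

**Size-matched baseline.**  The plug-in estimator is positively biased at
finite n, so each data estimate is compared with a baseline in which the
empirical sample is replaced by a single fresh draw of the same size from the
circular uniform, then put through the *identical* bootstrap.  Keeping the
two procedures symmetric is essential: both medians then carry the same two
layers of finite-sample bias (≈ (n_bins−1)/(N ln 2) bits in total at sample
size N), and under an independent observer the data median falls inside the
baseline's central 95% interval at the nominal rate.  An asymmetric baseline
(a fresh uniform sample per replicate) carries only one bias layer and flags
independent data as dependent.  Whether the original analyses resampled
trials or distances, and their exact bin-edge placement, is not documented;
both choices here are configurable and the defaults are stated above.

**RM-ANOVA** is the standard blocked one-way design (F = MS_level /
MS_level×subject), computed by `statsmodels` AnovaRM, without sphericity
correction.

## Ensemble encoders

Both models assume the observer sees only noisy observations
xᵢ ~ VM(θᵢ, κ_obs) of the true stimulus values and inverts a hierarchical
generative model; κ_obs ∈ {5, 10, 20} spans the range estimated from
set-size-one report errors.

**Two-level HBM.**  θᵢ | μₑ, κₑ ~ VM(μₑ, κₑ); μₑ ~ U(−π, π];
κₑ ~ U(0, 100).  The uniform κₑ bound of 100 is taken literally from the
prior.  Posterior stimulus estimates shrink toward the ensemble mean, more
strongly for lower κ_obs and for stimuli farther from the mean.

**von Mises finite mixture.**  K components (K fixed to the set size),
weights π ~ Dirichlet(α, …, α) with **per-component concentration α = 1**,
i.e. a uniform distribution over the weight simplex; μₖ ~ U(−π, π];
κₖ ~ Gamma(shape 1, rate β); β ~ Gamma(1, 1) (shape–rate convention
throughout).  The per-component parameterization is deliberate: the sparse
truncated-Dirichlet-process variant (concentration α/K) concentrates the
posterior on ~2 occupied components for six dispersed stimuli and produces
component-mean bias slopes roughly half the size of those this package (and
the analyses it replicates) obtains; it remains available by passing
`alpha = a/K`.  Per-draw assignments zᵢ give the occupied-component count
and, via the mean of the assigned component, a label-switching-safe
per-stimulus component mean (the circular mean over draws of μ_{zᵢ}).

**Inference.**  The posterior contract (draws from the stated joint
posterior) is met with a Gibbs sampler rather than gradient-based HMC:
every conditional except the concentrations is exact —

- θᵢ: product of two von Mises terms is von Mises (resultant-vector
  addition), sampled directly;
- μₑ, μₖ: von Mises on the cluster resultant;
- zᵢ: categorical (Gumbel-max); π: Dirichlet; β: conjugate Gamma;
- κₑ, κₖ: one-dimensional conditionals sampled by griddy Gibbs — κₑ on a
  512-point uniform grid over (0, 100) with within-cell jitter, κₖ on a
  384-point geometric grid over (10⁻³, 500) with log-cell jitter and the
  cell measure folded into the weights.  The κₖ upper bound truncates only
  negligible Gamma tail mass at these data sizes.

The sampler was validated against exact references: posterior stimulus means
for the HBM agree with 5-dimensional numerical quadrature to ~0.01 rad, and
mixture occupancy/co-assignment probabilities agree with full enumeration
over assignments (π integrated analytically, μₖ/κₖ/β numerically) to ~0.01.
Because whole-report trials are independent, the sampler runs one chain per
trial, batched: all trials advance in lock step through vectorized updates,
which is what makes hundreds of trials × thousands of draws feasible on one
CPU.  Reference MCMC settings are 5000 draws after 2000 tuning steps; Gibbs
needs no step-size adaptation, so the tuning phase is pure burn-in and
desk-scale runs use 1500–2000 draws after 500 burn-in.  Chains are
single-chain per trial; effective sample sizes (via arviz) are exposed in
`Results.diagnostics()`.

**Simulated reporting** follows observe → infer → point-estimate → round:
the point estimate is the circular mode of each stimulus posterior, computed
as the densest of 360 equal histogram bins (ties resolved toward the
circular mean), and rounding to the task's response grid happens after point
estimation, never inside inference.  Grid snapping breaks exact midpoint
ties toward the lower index for determinism.

## Bias analysis

The bias sample pairs each report's signed error with the signed distance
from the **presented** value to the relevant mean — the trial ensemble mean
(circular mean of presented values) or the inferred component mean.  With
this sign convention a positive OLS slope means attraction toward the mean.
The regression includes an intercept, restricts to distances in (−π/2, π/2)
where the bias function is approximately linear, and reports the slope's
two-sided t-test.  Alternatives — anchoring distances on the reported value,
or using the posterior ensemble mean μₑ — are config switches; the defaults
were chosen because they reproduce the published simulation coefficients on
three of the four hierarchical-model cells to the second decimal.  Trials
whose ensemble mean is undefined (zero resultant, e.g. all eight discrete
colors shown together) are excluded and logged.  For empirical data the
component means must be inferred; since participants' internal observations
are unavailable, the mixture is fitted to each trial's presented values
passed through the model's own observation channel at a configured κ_obs.

## Synthetic observers

The generators emulate the *statistical structure* the analyses assume:
uniform stimulus sampling (i.i.d. on the 360-value grid; without replacement
on the 8-value grid), von Mises memory noise, uniform guessing, and two
report-order policies — "confidence" (ascending realized noise magnitude, a
metacognition-free reading of report-in-order-of-confidence) and random.
The grouping observer orders reports along a greedy nearest-neighbour chain
through its remembered values, starting from the most confident one, and on
the discrete task never repeats a previously reported color (nearest unused
button).  Defaults: κ_report = 10 (the middle of the empirically plausible
observation-noise range), guess rate 0.1 (a typical mid-set-size lapse
share).

They do **not** emulate: swap/misbinding errors, inter-trial serial
dependence, stimulus-specific (cardinal/category) biases, participant
heterogeneity, or any sequential interaction between reports beyond
ordering.  A green calibration test therefore establishes that the KL
pipeline is calibrated for an independent observer and detects greedy
similarity grouping — not that it detects every form of dependence in human
data.

## Numerical choices and degenerate inputs

- κ̂ in the von Mises ML fit solves I₁(κ)/I₀(κ) = R by Brent's method and is
  capped at 10⁴ (circular SD ≈ 0.01 rad, far below either task's response
  resolution); all-identical samples hit the cap, zero-resultant samples
  return the uniform fit (κ̂ = 0).
- At or above the same cap the observation channel returns exact values.
- Circular means below resultant length 10⁻⁹ raise a zero-resultant error.
- Densities use exponentially scaled Bessel functions throughout, so large
  concentrations neither overflow nor lose the normalization.
- One master seed fans out to stage seeds via
  `SeedSequence([master, counter])`, keeping every pipeline stage
  independently reproducible and all derived seeds below 2³¹.

## Known limitations

- The discrete-task hierarchical simulation at κ_obs = 5 yields an
  ensemble-mean bias slope near 0.35: with stimuli confined to the 8-value
  grid (minimum separation π/4) the inferred ensemble is broader and the
  shrinkage weaker than with continuous stimulus sampling (slope ≈ 0.45).
  No single stimulus-sampling recipe reproduces all published discrete-task
  coefficients simultaneously; this package keeps the experiment-faithful
  8-value sampling for all discrete simulations.
- Full factorial repeated-measures designs (estimate type × report pair) are
  reduced to the one-way machinery plus paired comparisons.
- The mixture is a finite truncation, not a Dirichlet process; reports are
  not simulated sequentially (neither encoder has a temporal component); and
  model parameters are not fitted to human data by likelihood maximization —
  simulation and comparison only.
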