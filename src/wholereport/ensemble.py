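"""Hierarchical Bayesian ensemble encoders for whole-report trials.

Two observer models are implemented, both assuming the observer only sees
noisy von Mises observations ``x_i ~ VM(theta_i, kappa_obs)`` of the true
stimulus values and inverts a hierarchical generative model of the display:

* **Two-level hierarchical model (HBM)** — all N stimuli in a trial are
  samples from one "ensemble" von Mises distribution::

      theta_i | mu_e, kappa_e ~ VM(mu_e, kappa_e)
      mu_e ~ Uniform(-pi, pi],   kappa_e ~ Uniform(0, 100)

  Posterior stimulus estimates shrink toward the ensemble mean; the amount of
  shrinkage grows as ``kappa_obs`` falls.  ``kappa_obs`` is the model's only
  free parameter.

* **von Mises finite mixture (BFMM)** — stimuli are generated by one of K
  weighted von Mises components (a truncated Dirichlet-process construction),
  so similar stimuli are clustered and shrink toward their *component* mean::

      pi ~ Dirichlet(alpha, ..., alpha)
      mu_k ~ Uniform(-pi, pi],  kappa_k ~ Gamma(1, rate beta),  beta ~ Gamma(1, 1)
      z_i ~ Categorical(pi),    theta_i | z_i ~ VM(mu_{z_i}, kappa_{z_i})

Inference uses a Gibbs sampler with exact conditional updates for the
stimulus values, mean directions, mixture weights, assignments and the
Gamma-rate hyperparameter; the one-dimensional concentration conditionals
(``kappa_e``, ``kappa_k``) are drawn by griddy Gibbs on a fine grid.  Because
whole-report trials are mutually independent, the sampler runs *batched*: one
chain per trial, all trials advanced in lock step with vectorized updates,
which is what makes experiment-scale simulation (hundreds of trials x
thousands of draws) feasible on one CPU.

Simulated reporting follows the observe -> infer -> point-estimate -> round
pipeline: the circular mode of each stimulus posterior (360-bin histogram) is
snapped to the task's response grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .circular import KAPPA_CAP, TWO_PI, StimulusGrid, snap_to_grid, wrap_angle

__all__ = [
    "MCMCSettings",
    "HBMSpec",
    "BFMMSpec",
    "HierarchicalEnsembleModel",
    "VonMisesMixtureModel",
    "HBMResults",
    "BFMMResults",
    "WholeReportSimulation",
    "observe",
    "hbm_infer",
    "bfmm_infer",
    "posterior_point_estimate",
    "simulate_whole_report_trial",
    "simulate_whole_report_trials",
    "occupied_components",
    "component_mean_for_stimulus",
]

KAPPA_E_MAX = 100.0  # upper bound of the uniform prior on the ensemble concentration
KAPPA_K_MAX = 500.0  # griddy-Gibbs support for component concentrations (Gamma tail
#                      mass beyond this is negligible for every kappa_obs used here)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.  Defaults are the reference configuration
    (5000 draws after 2000 tuning steps, one chain per trial); tests and
    desk-scale runs reduce them explicitly."""

    draws: int = 5000
    tune: int = 2000
    chains: int = 1

    def __post_init__(self):
        if self.draws < 1 or self.tune < 0 or self.chains != 1:
            raise ValueError("draws >= 1, tune >= 0, chains == 1 required")


@dataclass(frozen=True)
class HBMSpec:
    """Two-level hierarchical model specification; ``kappa_obs`` (observation
    concentration) is the only free parameter."""

    kappa_obs: float
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self):
        if not self.kappa_obs > 0:
            raise ValueError("kappa_obs must be positive")


@dataclass(frozen=True)
class BFMMSpec:
    """Finite mixture specification.

    ``n_components`` (K) defaults to the set size.  ``alpha`` is the
    *per-component* Dirichlet concentration: the default ``alpha = 1`` puts a
    uniform distribution over the weight simplex (pass ``alpha = a/K`` to get
    the sparse truncated-Dirichlet-process construction with total mass a).
    """

    kappa_obs: float
    n_components: int | None = None
    alpha: float = 1.0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self):
        if not self.kappa_obs > 0:
            raise ValueError("kappa_obs must be positive")
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


def observe(theta, kappa_obs, rng):
    """Noisy von Mises observations ``x_i ~ VM(theta_i, kappa_obs)``.

    At or above the concentration cap the observation is exact (``x == theta``).
    """
    if not kappa_obs > 0:
        raise ValueError("kappa_obs must be positive")
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if kappa_obs >= KAPPA_CAP:
        return theta.copy()
    return wrap_angle(theta + rng.vonmises(0.0, kappa_obs, size=theta.shape))


# ---------------------------------------------------------------------------
# batched Gibbs samplers
# ---------------------------------------------------------------------------


def _log_i0(kappa):
    return np.log(special.i0e(kappa)) + kappa


def _gumbel_argmax(logw, rng):
    """Sample categorical indices along the last axis via the Gumbel-max trick."""
    return np.argmax(logw + rng.gumbel(size=logw.shape), axis=-1)


def _sample_vonmises(rng, mu, kappa):
    return wrap_angle(mu + rng.vonmises(np.zeros_like(kappa), kappa))


def _hbm_gibbs_batch(x, kappa_obs, draws, tune, rng, grid_size=512):
    """Gibbs sampler for the two-level HBM, one independent chain per trial.

    x : (T, N) observations.  Returns post-warmup draws:
    theta (draws, T, N), mu_e (draws, T), kappa_e (draws, T).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    T, N = x.shape
    h = KAPPA_E_MAX / grid_size
    grid = np.linspace(h / 2, KAPPA_E_MAX - h / 2, grid_size)
    log_i0_grid = _log_i0(grid)

    zx = np.exp(1j * x)
    theta = x.copy()
    mu_e = wrap_angle(np.angle(zx.sum(axis=1)))
    kappa_e = np.full(T, 1.0)

    out_theta = np.empty((draws, T, N), dtype=np.float32)
    out_mu = np.empty((draws, T), dtype=np.float32)
    out_kappa = np.empty((draws, T), dtype=np.float32)

    for it in range(tune + draws):
        # theta_i | rest: product of two von Mises terms -> von Mises
        c = kappa_obs * zx + (kappa_e * np.exp(1j * mu_e))[:, None]
        theta = _sample_vonmises(rng, np.angle(c), np.abs(c))
        # mu_e | theta, kappa_e (uniform prior)
        zres = np.exp(1j * theta).sum(axis=1)
        mu_e = _sample_vonmises(rng, np.angle(zres), kappa_e * np.abs(zres))
        # kappa_e | theta, mu_e on (0, 100): griddy Gibbs
        s = np.cos(theta - mu_e[:, None]).sum(axis=1)
        logw = s[:, None] * grid[None, :] - N * log_i0_grid[None, :]
        idx = _gumbel_argmax(logw, rng)
        kappa_e = np.clip(grid[idx] + rng.uniform(-h / 2, h / 2, size=T), 1e-6, KAPPA_E_MAX)
        if it >= tune:
            out_theta[it - tune] = theta
            out_mu[it - tune] = mu_e
            out_kappa[it - tune] = kappa_e
    return {"theta": out_theta, "mu_e": out_mu, "kappa_e": out_kappa}


def _kappa_k_grid(grid_size):
    grid = np.geomspace(1e-3, KAPPA_K_MAX, grid_size)
    dlog = np.log(grid[1]) - np.log(grid[0])
    log_width = np.log(grid) + np.log(dlog)  # cell measure of the geometric grid
    return grid, dlog, log_width


def _bfmm_gibbs_batch(x, kappa_obs, K, alpha, draws, tune, rng, grid_size=384):
    """Gibbs sampler for the von Mises finite mixture, one chain per trial.

    x : (T, N).  Returns post-warmup draws: theta (draws, T, N), z (draws, T, N),
    pi / mu / kappa (draws, T, K), beta (draws, T).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    T, N = x.shape
    grid, dlog, log_width = _kappa_k_grid(grid_size)
    log_i0_grid = _log_i0(grid)
    karange = np.arange(K)

    zx = np.exp(1j * x)
    theta = x.copy()
    z = np.tile(karange[:N] % K if N <= K else np.arange(N) % K, (T, 1)).astype(np.int64)
    pi = np.full((T, K), 1.0 / K)
    mu = wrap_angle(rng.uniform(-np.pi, np.pi, size=(T, K)))
    mu[:, : min(N, K)] = x[:, : min(N, K)]
    kap = np.full((T, K), 5.0)
    beta = np.ones(T)

    out = {
        "theta": np.empty((draws, T, N), dtype=np.float32),
        "z": np.empty((draws, T, N), dtype=np.int8),
        "pi": np.empty((draws, T, K), dtype=np.float32),
        "mu": np.empty((draws, T, K), dtype=np.float32),
        "kappa": np.empty((draws, T, K), dtype=np.float32),
        "beta": np.empty((draws, T), dtype=np.float32),
    }

    for it in range(tune + draws):
        # theta_i | z_i, component, x_i
        kap_z = np.take_along_axis(kap, z, axis=1)
        mu_z = np.take_along_axis(mu, z, axis=1)
        c = kappa_obs * zx + kap_z * np.exp(1j * mu_z)
        theta = _sample_vonmises(rng, np.angle(c), np.abs(c))
        # z_i | theta_i, pi, components
        log_like = kap[:, None, :] * np.cos(theta[:, :, None] - mu[:, None, :]) - _log_i0(
            kap
        )[:, None, :]
        z = _gumbel_argmax(np.log(pi)[:, None, :] + log_like, rng)
        onehot = z[:, :, None] == karange[None, None, :]
        counts = onehot.sum(axis=1)
        # pi | z  ~ Dirichlet(alpha + n_k)
        g = rng.gamma(alpha + counts)
        pi = g / g.sum(axis=1, keepdims=True)
        pi = np.clip(pi, 1e-300, None)
        pi /= pi.sum(axis=1, keepdims=True)
        # mu_k | theta in component k, kappa_k (uniform prior; empty -> uniform)
        cres = np.einsum("tnk,tn->tk", onehot, np.exp(1j * theta))
        mu = _sample_vonmises(rng, np.angle(cres), kap * np.abs(cres))
        # kappa_k | ... : Gamma(1, beta) prior x von Mises likelihoods, griddy Gibbs
        s = np.real(cres * np.exp(-1j * mu))  # sum cos(theta_i - mu_k) over members
        logw = (
            s[:, :, None] * grid[None, None, :]
            - counts[:, :, None] * log_i0_grid[None, None, :]
            - beta[:, None, None] * grid[None, None, :]
            + log_width[None, None, :]
        )
        idx = _gumbel_argmax(logw, rng)
        kap = grid[idx] * np.exp(rng.uniform(-dlog / 2, dlog / 2, size=(T, K)))
        kap = np.clip(kap, 1e-4, KAPPA_K_MAX)
        # beta | kappa_1..K : conjugate Gamma update
        beta = rng.gamma(1.0 + K, 1.0 / (1.0 + kap.sum(axis=1)))
        if it >= tune:
            j = it - tune
            out["theta"][j] = theta
            out["z"][j] = z
            out["pi"][j] = pi
            out["mu"][j] = mu
            out["kappa"][j] = kap
            out["beta"][j] = beta
    return out


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def _circ_mean_axis(angles, axis=0):
    z = np.exp(1j * angles).sum(axis=axis)
    return wrap_angle(np.angle(z))


def _histogram_mode(draws, n_bins=360):
    """Circular mode of posterior draws via an equal-bin histogram.

    ``draws`` has shape (n_draws, ...); the mode is computed independently
    over the leading axis.  Ties go to the bin centre nearest the circular
    mean of the draws.
    """
    draws = np.asarray(draws, dtype=float)
    n_draws = draws.shape[0]
    flat = draws.reshape(n_draws, -1)
    m = flat.shape[1]
    width = TWO_PI / n_bins
    idx = np.clip(((flat + np.pi) / width).astype(np.int64), 0, n_bins - 1)
    offsets = np.arange(m, dtype=np.int64) * n_bins
    counts = np.bincount((idx + offsets[None, :]).ravel(), minlength=m * n_bins).reshape(
        m, n_bins
    )
    centers = -np.pi + (np.arange(n_bins) + 0.5) * width
    cmean = _circ_mean_axis(flat, axis=0)
    penalty = np.abs(wrap_angle(centers[None, :] - cmean[:, None]))
    best = np.where(counts == counts.max(axis=1, keepdims=True), penalty, np.inf).argmin(
        axis=1
    )
    return centers[best].reshape(draws.shape[1:])


def posterior_point_estimate(samples, n_bins=360):
    """Point estimate of a circular posterior: the densest of ``n_bins`` equal
    histogram bins (its centre); ties resolved toward the circular mean.

    Requires at least 100 draws (the histogram mode is meaningless below that).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if samples.size < 100:
        raise ValueError("need at least 100 posterior draws for a mode estimate")
    return float(_histogram_mode(samples[:, None], n_bins=n_bins)[0])


def _ess(chain):
    """Effective sample size of a single chain (via arviz)."""
    chain = np.asarray(chain, dtype=float)
    if chain.size < 4 or np.allclose(chain, chain[0]):
        return float(chain.size)
    import arviz  # deferred: slow import, only needed for diagnostics

    return float(arviz.ess(chain[None, :]))


class _ResultsBase:
    """Posterior draws for one whole-report trial (statsmodels-style Results)."""

    def __init__(self, model, draws_dict, batch_index=0):
        self.model = model
        self._draws = draws_dict
        self._t = batch_index

    @property
    def n_draws(self):
        return self._draws["theta"].shape[0]

    @property
    def theta(self):
        """Posterior draws of the stimulus values, shape (draws, N)."""
        return np.asarray(self._draws["theta"][:, self._t, :], dtype=float)

    def point_estimates(self, grid: StimulusGrid | None = None):
        """Circular-mode point estimate per stimulus, optionally snapped to a
        response grid (rounding happens here, never inside inference)."""
        est = _histogram_mode(self.theta)
        if grid is not None:
            est = snap_to_grid(est, grid)
        return est

    def diagnostics(self):
        """Effective sample sizes for the trial's key chains."""
        theta = self.theta
        ess_theta = [_ess(np.unwrap(theta[:, i])) for i in range(theta.shape[1])]
        out = {"ess_theta_min": float(min(ess_theta)), "n_draws": self.n_draws}
        return out

    def summary(self):
        theta = self.theta
        rows = []
        for i in range(theta.shape[1]):
            rows.append(self._angle_row(f"theta[{i}]", theta[:, i]))
        rows.extend(self._extra_rows())
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "ess"]).set_index(
            "parameter"
        )

    @staticmethod
    def _angle_row(name, draws):
        r = np.abs(np.exp(1j * draws).mean())
        circ_sd = float(np.sqrt(-2.0 * np.log(max(r, 1e-300))))
        return (name, float(_circ_mean_axis(draws)), circ_sd, _ess(np.unwrap(draws)))

    @staticmethod
    def _scalar_row(name, draws):
        return (name, float(np.mean(draws)), float(np.std(draws)), _ess(draws))

    def _extra_rows(self):
        return []


class HBMResults(_ResultsBase):
    """Posterior for the two-level hierarchical model."""

    @property
    def ensemble_mean(self):
        """Draws of mu_e, shape (draws,)."""
        return np.asarray(self._draws["mu_e"][:, self._t], dtype=float)

    @property
    def ensemble_kappa(self):
        return np.asarray(self._draws["kappa_e"][:, self._t], dtype=float)

    def _extra_rows(self):
        return [
            self._angle_row("mu_e", self.ensemble_mean),
            self._scalar_row("kappa_e", self.ensemble_kappa),
        ]


class BFMMResults(_ResultsBase):
    """Posterior for the von Mises finite mixture."""

    @property
    def weights(self):
        return np.asarray(self._draws["pi"][:, self._t, :], dtype=float)

    @property
    def component_means(self):
        return np.asarray(self._draws["mu"][:, self._t, :], dtype=float)

    @property
    def component_kappas(self):
        return np.asarray(self._draws["kappa"][:, self._t, :], dtype=float)

    @property
    def assignments(self):
        return np.asarray(self._draws["z"][:, self._t, :], dtype=int)

    @property
    def beta(self):
        return np.asarray(self._draws["beta"][:, self._t], dtype=float)

    def occupied_components(self):
        """Normalised histogram over the number of occupied components (1..K)."""
        z = self.assignments
        k = self.model.n_components
        occ = (z[:, :, None] == np.arange(k)[None, None, :]).any(axis=1).sum(axis=1)
        hist = np.bincount(occ, minlength=k + 1)[1:].astype(float)
        return hist / hist.sum()

    def component_mean_for_stimulus(self, i):
        """Circular mean over draws of the mean of the component stimulus ``i``
        is assigned to (label-switching-safe aggregation)."""
        mu = self.component_means
        z = self.assignments[:, i]
        per_draw = mu[np.arange(mu.shape[0]), z]
        return float(_circ_mean_axis(per_draw))

    def _extra_rows(self):
        rows = [self._scalar_row("beta", self.beta)]
        k = self.model.n_components
        for j in range(k):
            rows.append(self._scalar_row(f"pi[{j}]", self.weights[:, j]))
        return rows


class HierarchicalEnsembleModel:
    """Two-level hierarchical Bayesian encoder for one whole-report trial.

    Parameters
    ----------
    observations : array_like
        Noisy observations ``x_1..N`` (radians, any wrapping).
    kappa_obs : float
        Observation concentration — the model's only free parameter.

    Examples
    --------
    >>> model = HierarchicalEnsembleModel([0.1, -0.2, 0.3], kappa_obs=5.0)
    >>> res = model.fit(draws=1000, tune=500, seed=0)
    >>> res.point_estimates(StimulusGrid(360))  # doctest: +SKIP
    """

    def __init__(self, observations, kappa_obs):
        self.observations = wrap_angle(np.atleast_1d(np.asarray(observations, dtype=float)))
        if self.observations.ndim != 1 or self.observations.size < 1:
            raise ValueError("observations must be a nonempty 1-D array of angles")
        if not kappa_obs > 0:
            raise ValueError("kappa_obs must be positive")
        self.kappa_obs = float(kappa_obs)

    @property
    def n_stimuli(self):
        return self.observations.size

    @classmethod
    def from_spec(cls, observations, spec: HBMSpec):
        return cls(observations, spec.kappa_obs)

    def fit(self, draws=5000, tune=2000, seed=None) -> HBMResults:
        rng = np.random.default_rng(seed)
        sampled = _hbm_gibbs_batch(
            self.observations[None, :], self.kappa_obs, draws, tune, rng
        )
        return HBMResults(self, sampled)


class VonMisesMixtureModel:
    """Bayesian finite mixture encoder (K weighted von Mises components).

    ``n_components`` defaults to the number of observations, matching the
    convention of fixing K to the set size; ``alpha`` is the per-component
    symmetric Dirichlet concentration (1 = uniform over the weight simplex).
    """

    def __init__(self, observations, kappa_obs, n_components=None, alpha=1.0):
        self.observations = wrap_angle(np.atleast_1d(np.asarray(observations, dtype=float)))
        if self.observations.ndim != 1 or self.observations.size < 1:
            raise ValueError("observations must be a nonempty 1-D array of angles")
        if not kappa_obs > 0:
            raise ValueError("kappa_obs must be positive")
        self.kappa_obs = float(kappa_obs)
        self.n_components = int(n_components) if n_components else self.observations.size
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not alpha > 0:
            raise ValueError("alpha must be positive")
        self.alpha = float(alpha)

    @classmethod
    def from_spec(cls, observations, spec: BFMMSpec):
        return cls(observations, spec.kappa_obs, spec.n_components, spec.alpha)

    def fit(self, draws=5000, tune=2000, seed=None) -> BFMMResults:
        rng = np.random.default_rng(seed)
        sampled = _bfmm_gibbs_batch(
            self.observations[None, :],
            self.kappa_obs,
            self.n_components,
            self.alpha,
            draws,
            tune,
            rng,
        )
        return BFMMResults(self, sampled)


def hbm_infer(x, spec: HBMSpec, seed=None) -> HBMResults:
    """Sample the HBM posterior for one trial's observations (thin functional
    wrapper over :class:`HierarchicalEnsembleModel`)."""
    return HierarchicalEnsembleModel.from_spec(x, spec).fit(
        draws=spec.mcmc.draws, tune=spec.mcmc.tune, seed=seed
    )


def bfmm_infer(x, spec: BFMMSpec, seed=None) -> BFMMResults:
    """Sample the mixture posterior for one trial's observations."""
    return VonMisesMixtureModel.from_spec(x, spec).fit(
        draws=spec.mcmc.draws, tune=spec.mcmc.tune, seed=seed
    )


def occupied_components(posterior):
    """Distribution over the number of occupied components of a mixture
    posterior; rejects HBM posteriors, which have no assignments."""
    if not isinstance(posterior, BFMMResults):
        raise TypeError("occupied_components requires a mixture (BFMM) posterior")
    return posterior.occupied_components()


def component_mean_for_stimulus(posterior, i):
    if not isinstance(posterior, BFMMResults):
        raise TypeError("component_mean_for_stimulus requires a mixture (BFMM) posterior")
    return posterior.component_mean_for_stimulus(i)


# ---------------------------------------------------------------------------
# whole-report simulation
# ---------------------------------------------------------------------------


@dataclass
class WholeReportSimulation:
    """Batched simulation output: one row per trial, one column per stimulus.

    ``reported`` is the grid-snapped report; ``point_estimates`` the raw
    posterior modes; ``component_means`` (mixture only) the label-switching-
    safe posterior mean of the component generating each stimulus;
    ``occupied_hist`` (mixture only) the per-trial distribution of occupied
    component counts.
    """

    presented: np.ndarray
    observations: np.ndarray
    point_estimates: np.ndarray
    reported: np.ndarray
    component_means: np.ndarray | None = None
    occupied_hist: np.ndarray | None = None

    @property
    def n_trials(self):
        return self.presented.shape[0]

    def modal_occupied(self):
        if self.occupied_hist is None:
            raise TypeError("occupied-component counts exist only for mixture simulations")
        return np.argmax(self.occupied_hist, axis=1) + 1


def simulate_whole_report_trials(theta, grid: StimulusGrid, spec, seed=None) -> WholeReportSimulation:
    """Simulate whole-report trials under an ensemble encoder, batched.

    For every trial (row of ``theta``): draw noisy observations with
    ``spec.kappa_obs``, sample the model posterior, take the circular mode of
    each stimulus posterior, and snap it to ``grid``.

    Parameters
    ----------
    theta : (T, N) array
        True stimulus values, on the task grid.
    grid : StimulusGrid
        Response grid (360 continuous / 8 discrete).
    spec : HBMSpec or BFMMSpec
    seed : int or numpy Generator, optional
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = observe(theta, spec.kappa_obs, rng)
    mcmc = spec.mcmc
    if isinstance(spec, HBMSpec):
        sampled = _hbm_gibbs_batch(x, spec.kappa_obs, mcmc.draws, mcmc.tune, rng)
        comp_means = None
        occupied = None
    elif isinstance(spec, BFMMSpec):
        K = spec.n_components or theta.shape[1]
        sampled = _bfmm_gibbs_batch(
            x, spec.kappa_obs, K, spec.alpha, mcmc.draws, mcmc.tune, rng
        )
        mu = sampled["mu"]  # (draws, T, K)
        z = sampled["z"].astype(np.int64)  # (draws, T, N)
        per_draw = np.take_along_axis(mu, z, axis=2)
        comp_means = _circ_mean_axis(per_draw, axis=0)
        occupied = _occupied_hist(z, K)
    else:
        raise TypeError(f"unknown model spec {type(spec).__name__}")

    point = _histogram_mode(sampled["theta"])
    reported = snap_to_grid(point, grid)
    return WholeReportSimulation(
        presented=theta,
        observations=x,
        point_estimates=point,
        reported=reported,
        component_means=comp_means,
        occupied_hist=occupied,
    )


def _occupied_hist(z, K, chunk=500):
    """Per-trial normalised histogram of occupied-component counts, (T, K)."""
    draws, T, _ = z.shape
    hist = np.zeros((T, K), dtype=float)
    for start in range(0, draws, chunk):
        part = z[start : start + chunk]
        occ = (part[:, :, :, None] == np.arange(K)[None, None, None, :]).any(axis=2).sum(
            axis=2
        )
        for t in range(T):
            hist[t] += np.bincount(occ[:, t], minlength=K + 1)[1:]
    return hist / hist.sum(axis=1, keepdims=True)


def simulate_whole_report_trial(theta, grid: StimulusGrid, spec, seed=None):
    """Single-trial convenience wrapper: returns the snapped reports (length N)."""
    sim = simulate_whole_report_trials(np.atleast_2d(theta), grid, spec, seed=seed)
    return sim.reported[0]
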