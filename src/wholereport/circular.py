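"""Circular (directional) primitives used throughout the package.

All angles live in radians on the half-open interval ``(-pi, pi]``.  A single
wrapping convention — half-open at ``-pi`` — is enforced at every boundary so
that downstream arithmetic (relative distances, bias regressions, grid
snapping) never has to reason about equivalent representations of the same
direction.

The module provides angle arithmetic, circular summary statistics (circular
mean, mean resultant vector length), the von Mises distribution (density,
sampling, maximum-likelihood fitting), the discrete Kullback–Leibler
divergence against a uniform reference, and snapping to equispaced stimulus
grids (360 values for the continuous colour wheel, 8 for the discrete button
response array).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "TWO_PI",
    "KAPPA_CAP",
    "VonMisesParams",
    "StimulusGrid",
    "ZeroResultantError",
    "wrap_angle",
    "circ_dist",
    "circ_mean",
    "mrvl",
    "vm_density",
    "vm_sample",
    "vm_mle_fit",
    "kl_divergence_uniform",
    "snap_to_grid",
]

TWO_PI = 2.0 * np.pi

#: Concentration cap.  The von Mises MLE diverges for degenerate (all equal)
#: samples; at kappa = 1e4 the distribution's circular SD is ~0.01 rad, far
#: below either task's report resolution, so the cap is behaviourally exact.
KAPPA_CAP = 1.0e4


class ZeroResultantError(ValueError):
    """The circular mean is undefined: the resultant vector has zero length."""


def wrap_angle(x):
    """Wrap angle(s) in radians onto ``(-pi, pi]``.

    Idempotent and 2*pi-periodic: ``wrap(wrap(x)) == wrap(x)`` and
    ``wrap(x + 2*pi) == wrap(x)``.  The boundary ``-pi`` maps to ``+pi``.

    Parameters
    ----------
    x : float or array_like
        Angle(s) in radians; must be finite.

    Returns
    -------
    float or ndarray
        Wrapped angle(s) in ``(-pi, pi]``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angles must be finite")
    wrapped = np.pi - np.mod(np.pi - x, TWO_PI)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def circ_dist(a, b):
    """Signed circular distance ``wrap(a - b)`` in ``(-pi, pi]``.

    Antisymmetric up to the pi boundary: ``circ_dist(a, b) == -circ_dist(b, a)``
    except when the distance is exactly pi.
    """
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def _resultant(angles):
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(1j * angles).sum()
    return z, angles.size


def circ_mean(angles, tol=1e-9):
    """Circular mean: the argument of the summed unit vectors.

    Raises
    ------
    ZeroResultantError
        If the mean resultant length falls below ``tol`` (e.g. an antipodal
        pair, or all eight colours of the discrete task), where the circular
        mean is undefined.
    """
    z, n = _resultant(angles)
    if np.abs(z) / n < tol:
        raise ZeroResultantError(
            f"circular mean undefined: resultant length {np.abs(z) / n:.3g} < {tol:.3g}"
        )
    return wrap_angle(np.angle(z))


def mrvl(angles):
    """Mean resultant vector length, ``|sum exp(i*theta)| / n`` in [0, 1].

    1 means all angles identical (perfect concentration); 0 means the unit
    vectors cancel (maximal dispersion).
    """
    z, n = _resultant(angles)
    return float(np.abs(z) / n)


@dataclass(frozen=True)
class VonMisesParams:
    """Parameters of a von Mises (circular normal) distribution.

    Attributes
    ----------
    mu : float
        Mean direction in ``(-pi, pi]``.
    kappa : float
        Concentration (>= 0); ``kappa = 0`` is the circular uniform and large
        kappa approaches a point mass (roughly analogous to 1/sigma^2).
    """

    mu: float
    kappa: float

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and >= 0")
        object.__setattr__(self, "mu", wrap_angle(self.mu))


def vm_density(x, params: VonMisesParams):
    """von Mises density ``exp(kappa*cos(x - mu)) / (2*pi*I0(kappa))``.

    Evaluated with the exponentially scaled Bessel function so that large
    concentrations do not overflow.  ``kappa = 0`` gives the uniform density
    ``1/(2*pi)`` everywhere.
    """
    x = np.asarray(x, dtype=float)
    kappa = params.kappa
    # exp(k cos d)/I0(k) == exp(k (cos d - 1))/i0e(k), stable for large k
    out = np.exp(kappa * (np.cos(x - params.mu) - 1.0)) / (TWO_PI * special.i0e(kappa))
    return float(out) if out.ndim == 0 else out


def vm_sample(params: VonMisesParams, n, rng):
    """Draw ``n`` i.i.d. von Mises angles, wrapped to ``(-pi, pi]``.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed;
    identical seeds give identical outputs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if params.kappa >= KAPPA_CAP:
        return np.full(int(n), params.mu, dtype=float)
    return wrap_angle(rng.vonmises(params.mu, params.kappa, size=int(n)))


def _a1(kappa):
    """Ratio I1(kappa)/I0(kappa), the mean resultant length of a VM(mu, kappa)."""
    return special.i1e(kappa) / special.i0e(kappa)


def vm_mle_fit(angles, kappa_cap=KAPPA_CAP):
    """Maximum-likelihood von Mises fit ``(mu_hat, kappa_hat)``.

    ``mu_hat`` is the circular mean and ``kappa_hat`` solves
    ``I1(k)/I0(k) = R`` (the sample mean resultant length).  Degenerate
    samples whose ``R`` exceeds what ``kappa_cap`` can produce get
    ``kappa_hat = kappa_cap``; a zero resultant gives the uniform fit
    ``(0, 0)``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty input")
    z, n = _resultant(angles)
    r = np.abs(z) / n
    if r <= 1e-12:
        return VonMisesParams(0.0, 0.0)
    mu_hat = wrap_angle(np.angle(z))
    if r >= _a1(kappa_cap):
        return VonMisesParams(mu_hat, float(kappa_cap))
    kappa_hat = optimize.brentq(lambda k: _a1(k) - r, 1e-12, kappa_cap)
    return VonMisesParams(mu_hat, float(kappa_hat))


def kl_divergence_uniform(counts):
    """Plug-in KL divergence (bits) of binned counts from the uniform reference.

    ``D = sum_x P(x) log2(P(x)/Q(x))`` with ``Q = 1/n_bins`` and the
    convention ``0*log 0 = 0``; no pseudocounts are added (Q is strictly
    positive so the plug-in estimator is finite).  Bounded by ``log2(n_bins)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need counts over at least 2 bins")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    q = np.full(counts.size, 1.0 / counts.size)
    return float(stats.entropy(counts / total, q, base=2))


@dataclass(frozen=True)
class StimulusGrid:
    """``m`` equispaced response values with index 0 at angle 0.

    The continuous task grid has m = 360 (one value per degree of the colour
    wheel); the discrete task grid has m = 8 (the eight response buttons,
    multiples of 45 degrees).
    """

    m: int
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if int(self.m) < 1:
            raise ValueError("grid size must be >= 1")
        object.__setattr__(self, "m", int(self.m))
        vals = wrap_angle(TWO_PI * np.arange(self.m) / self.m)
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def spacing(self):
        return TWO_PI / self.m

    def index_of(self, x, atol=1e-9):
        """Grid index of on-grid angle(s); raises if any value is off-grid."""
        x = wrap_angle(x)
        idx = np.mod(np.rint(np.asarray(x) / self.spacing), self.m).astype(int)
        if not np.allclose(circ_dist(x, self.values[idx]), 0.0, atol=atol):
            raise ValueError("value is not on the stimulus grid")
        return int(idx) if idx.ndim == 0 else idx

    def contains(self, x, atol=1e-9):
        try:
            self.index_of(x, atol=atol)
        except ValueError:
            return False
        return True


def snap_to_grid(x, grid: StimulusGrid):
    """Nearest grid value by circular distance; exact midpoints take the
    lower-index neighbour (deterministic tie rule)."""
    x = wrap_angle(x)
    r = np.mod(np.asarray(x, dtype=float), TWO_PI) / grid.spacing  # in [0, m)
    lower = np.floor(r)
    frac = r - lower
    idx = np.mod(np.where(frac > 0.5, lower + 1.0, lower), grid.m).astype(int)
    out = grid.values[idx]
    return float(out) if np.ndim(x) == 0 else out
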