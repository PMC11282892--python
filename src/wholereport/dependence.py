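"""Within-trial report dependence: relative distances, bootstrapped KL
divergence against a circular uniform, and MRVL summaries.

If stimuli were encoded and reported independently, the signed circular
distance between two values reported in the same trial would be uniform on
the circle.  The analysis bins relative distances into equal arcs (36 for
the continuous task, 8 for the discrete task), computes the plug-in KL
divergence from the uniform reference, and bootstraps it (1000 resamples).
Because the plug-in estimator is positively biased at finite n, each
empirical estimate is compared against a *size-matched baseline*: the same
procedure run on a fresh uniform sample of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import TWO_PI, circ_dist, kl_divergence_uniform, mrvl
from .task import SessionDataset, pooled_error_table

__all__ = [
    "RelativeDistanceSample",
    "KLEstimate",
    "AnovaResult",
    "relative_distances",
    "kl_bootstrap",
    "kl_baseline",
    "dependence_report",
    "mrvl_summary",
    "rm_anova_oneway",
]

N_BINS = {"continuous": 36, "discrete": 8}


@dataclass(frozen=True)
class RelativeDistanceSample:
    """Signed distances ``circ_dist(report_j, report_i)`` for one report pair
    (1-based positions, i < j), one entry per trial with set size >= j."""

    pair: tuple
    distances: np.ndarray

    @property
    def n(self):
        return self.distances.size


@dataclass(frozen=True)
class KLEstimate:
    """Bootstrap summary of the KL divergence from uniform (bits)."""

    median_bits: float
    q025: float
    q975: float
    n_boot: int
    n_bins: int
    sample_size: int
    is_baseline: bool = False

    def __post_init__(self):
        bound = np.log2(self.n_bins)
        if not (0.0 <= self.median_bits <= bound + 1e-12):
            raise ValueError("median KL outside [0, log2 n_bins]")


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    F: float
    df_effect: int
    df_error: int
    p: float


def relative_distances(dataset: SessionDataset, pair) -> RelativeDistanceSample:
    """Relative distance sample for report positions ``pair = (i, j)``.

    The distance is signed, later report minus earlier report, preserving
    the attraction-vs-avoidance direction of the dependence.
    """
    i, j = pair
    if not (1 <= i < j):
        raise ValueError("need report positions 1 <= i < j")
    max_n = max(dataset.set_sizes(), default=0)
    if j > max_n:
        raise ValueError(f"pair {pair} out of range for max set size {max_n}")
    d = [
        circ_dist(t.reported[j - 1], t.reported[i - 1])
        for t in dataset.trials
        if t.set_size >= j
    ]
    return RelativeDistanceSample(pair=(i, j), distances=np.asarray(d, dtype=float))


def _bin_counts(distances, n_bins):
    """Counts over ``n_bins`` equal arcs with a bin *centred* at zero
    (edges at +-pi/n_bins, ...), so near-zero distances share one bin."""
    idx = np.mod(np.rint(np.asarray(distances) / (TWO_PI / n_bins)).astype(int), n_bins)
    return np.bincount(idx, minlength=n_bins)


def _kl_from_multinomial(counts_matrix):
    p = counts_matrix / counts_matrix.sum(axis=1, keepdims=True)
    n_bins = counts_matrix.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p * n_bins), 0.0)
    return terms.sum(axis=1)


def _summarize(kls, n_boot, n_bins, size, is_baseline):
    return KLEstimate(
        median_bits=float(np.median(kls)),
        q025=float(np.quantile(kls, 0.025)),
        q975=float(np.quantile(kls, 0.975)),
        n_boot=n_boot,
        n_bins=n_bins,
        sample_size=size,
        is_baseline=is_baseline,
    )


def kl_bootstrap(sample: RelativeDistanceSample, n_bins, n_boot=1000, seed=None) -> KLEstimate:
    """Bootstrapped KL divergence of a relative-distance sample from uniform.

    Each replicate resamples the distances with replacement (equivalently:
    draws bin counts from a multinomial on the empirical bin frequencies),
    bins them, and evaluates the plug-in KL; the median and central 95%
    quantiles of the replicates are reported.
    """
    if sample.n == 0:
        raise ValueError("empty relative-distance sample")
    rng = np.random.default_rng(seed)
    counts = _bin_counts(sample.distances, n_bins)
    kl_divergence_uniform(counts)  # validates bins/counts
    boot = rng.multinomial(sample.n, counts / counts.sum(), size=n_boot)
    return _summarize(_kl_from_multinomial(boot), n_boot, n_bins, sample.n, False)


def kl_baseline(sample_size, n_bins, n_boot=1000, seed=None) -> KLEstimate:
    """Size-matched uniform baseline for :func:`kl_bootstrap`.

    The empirical sample is replaced by a single fresh draw of
    ``sample_size`` values from the circular uniform, and then put through
    *exactly* the same bootstrap as the data.  Keeping the two procedures
    symmetric (one observed sample, resampled with replacement) is what makes
    the comparison calibrated: both medians carry the same two layers of
    finite-sample plug-in bias.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(sample_size, np.full(n_bins, 1.0 / n_bins))
    boot = rng.multinomial(sample_size, counts / counts.sum(), size=n_boot)
    return _summarize(_kl_from_multinomial(boot), n_boot, n_bins, sample_size, True)


def consecutive_pairs(max_set_size):
    return [(i, i + 1) for i in range(1, max_set_size)]


def first_vs_later_pairs(max_set_size):
    return [(1, j) for j in range(2, max_set_size + 1)]


def dependence_report(datasets, pairs=None, n_boot=1000, seed=None) -> pd.DataFrame:
    """Data-vs-baseline KL table over report pairs.

    Parameters
    ----------
    datasets : SessionDataset or list of SessionDataset
        One entry per participant.
    pairs : list of (i, j), optional
        Report pairs; defaults to first-vs-later pairs up to the maximum set
        size, the layout of the torus/joint-distribution figures.
    n_boot, seed : bootstrap settings.

    Returns one row per (participant, pair) with the data and baseline
    medians and central-95% bands, and an ``exceeds_baseline`` flag (data
    median above the baseline's 97.5% quantile).
    """
    if isinstance(datasets, SessionDataset):
        datasets = [datasets]
    rng = np.random.default_rng(seed)
    rows = []
    for ds in datasets:
        n_bins = N_BINS[ds.task]
        max_n = max(ds.set_sizes())
        use_pairs = pairs or first_vs_later_pairs(max_n)
        for pair in use_pairs:
            if pair[1] > max_n:
                continue
            sample = relative_distances(ds, pair)
            if sample.n == 0:
                continue
            sub = rng.integers(0, 2**31 - 1, size=2)
            data = kl_bootstrap(sample, n_bins, n_boot=n_boot, seed=int(sub[0]))
            base = kl_baseline(sample.n, n_bins, n_boot=n_boot, seed=int(sub[1]))
            rows.append(
                {
                    "participant": ds.participant_id,
                    "condition": ds.condition,
                    "pair_i": pair[0],
                    "pair_j": pair[1],
                    "n": sample.n,
                    "data_median": data.median_bits,
                    "data_q025": data.q025,
                    "data_q975": data.q975,
                    "baseline_median": base.median_bits,
                    "baseline_q025": base.q025,
                    "baseline_q975": base.q975,
                    "exceeds_baseline": data.median_bits > base.q975,
                    "within_baseline": base.q025 <= data.median_bits <= base.q975,
                }
            )
    return pd.DataFrame(rows)


def mrvl_summary(dataset: SessionDataset, min_reports=2) -> pd.DataFrame:
    """MRVL of pooled report errors by set size, and by set size x report
    order.  Rows with ``report_order`` NaN are the per-set-size cells.
    Cells with fewer than ``min_reports`` reports are flagged and left NaN.
    """
    table = pooled_error_table(dataset)
    rows = []

    def cell(set_size, report_order, errors):
        ok = len(errors) >= min_reports
        rows.append(
            {
                "set_size": set_size,
                "report_order": report_order,
                "n": len(errors),
                "mrvl": mrvl(errors) if ok else np.nan,
                "flagged": not ok,
            }
        )

    for set_size, g in table.groupby("set_size"):
        cell(set_size, np.nan, g["error"].to_numpy())
        for order, gg in g.groupby("report_order"):
            cell(set_size, order, gg["error"].to_numpy())
    return pd.DataFrame(rows)


def rm_anova_oneway(matrix) -> AnovaResult:
    """One-way repeated-measures ANOVA, subjects as the blocking factor.

    ``matrix`` is subjects x levels (complete).  F = MS_level / MS_(level x
    subject); p from the F(df_effect, df_error) distribution, without
    sphericity correction.
    """
    from statsmodels.stats.anova import AnovaRM

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a complete subjects x levels matrix, at least 2x2")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be complete (no missing cells)")
    s, l = matrix.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(s), l),
            "level": np.tile(np.arange(l), s),
            "y": matrix.ravel(),
        }
    )
    res = AnovaRM(long, depvar="y", subject="subject", within=["level"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult(
        F=float(row["F Value"]),
        df_effect=int(row["Num DF"]),
        df_error=int(row["Den DF"]),
        p=float(row["Pr > F"]),
    )
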