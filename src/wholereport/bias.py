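"""Ensemble-mean and component-mean bias functions and their restricted OLS.

Hierarchical ensemble encoders predict that reports are displaced toward the
mean of the trial ensemble (two-level model) or of the similarity cluster a
stimulus belongs to (mixture model).  The bias is quantified by ordinary
least squares of the signed report error on the signed distance from the
stimulus to the relevant mean, restricted to distances in (-pi/2, pi/2)
where the bias function is approximately linear.  With both error and
distance measured from the presented value, a *positive* slope means
attraction toward the mean and a negative slope repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .circular import TWO_PI, ZeroResultantError, circ_dist, circ_mean
from .ensemble import BFMMSpec, _bfmm_gibbs_batch, _circ_mean_axis, observe
from .task import SessionDataset, TrialRecord

__all__ = [
    "BiasRegressionResult",
    "ensemble_mean_of_trial",
    "build_bias_sample",
    "bias_sample_from_arrays",
    "bias_regression",
    "bias_function",
]

DOMAIN_HALF_WIDTH = np.pi / 2


@dataclass(frozen=True)
class BiasRegressionResult:
    """OLS of report error on distance-to-mean over the restricted domain.

    ``p`` is the two-sided t-test p-value of the slope; ``n_used`` counts the
    in-domain rows actually regressed.
    """

    slope: float
    intercept: float
    r_squared: float
    p: float
    n_used: int
    domain: tuple = (-DOMAIN_HALF_WIDTH, DOMAIN_HALF_WIDTH)
    report_order: object = None

    def summary(self):
        lab = "all reports" if self.report_order is None else f"report {self.report_order}"
        return (
            f"bias regression ({lab}): slope={self.slope:.4f} "
            f"intercept={self.intercept:.4f} R^2={self.r_squared:.4f} "
            f"p={self.p:.3g} n={self.n_used}"
        )


def ensemble_mean_of_trial(trial: TrialRecord):
    """Circular mean of the trial's presented values.

    Raises :class:`ZeroResultantError` when undefined (e.g. all eight colours
    of the discrete task presented together); such trials are excluded from
    the bias analysis.
    """
    if trial.set_size < 2:
        raise ValueError("ensemble mean needs at least two stimuli")
    return circ_mean(trial.presented)


def bias_sample_from_arrays(presented, reported, means, mean_kind="ensemble",
                            anchor="presented", trial_ids=None) -> pd.DataFrame:
    """Assemble a bias table from aligned (T, N) arrays.

    ``means`` is either one mean per trial (shape (T,)) or one per stimulus
    (shape (T, N), e.g. component means).  ``anchor`` selects whether the
    distance is measured from the presented or the reported value.
    """
    presented = np.atleast_2d(np.asarray(presented, dtype=float))
    reported = np.atleast_2d(np.asarray(reported, dtype=float))
    t, n = presented.shape
    means = np.asarray(means, dtype=float)
    if means.ndim == 1:
        means = np.broadcast_to(means[:, None], (t, n))
    anchor_vals = presented if anchor == "presented" else reported
    err = circ_dist(reported, presented)
    dist = circ_dist(means, anchor_vals)
    if trial_ids is None:
        trial_ids = np.arange(t)
    frame = pd.DataFrame(
        {
            "trial_id": np.repeat(np.asarray(trial_ids), n),
            "stimulus": np.tile(np.arange(n), t),
            "report_order": np.tile(np.arange(1, n + 1), t),
            "error": err.ravel(),
            "distance_to_mean": dist.ravel(),
            "mean_kind": mean_kind,
        }
    )
    return frame


def _component_means_for_dataset(dataset, spec: BFMMSpec, seed):
    """Infer per-stimulus component means for every trial of a dataset.

    Participants' internal observations are unavailable, so each trial's
    presented values are passed through the model's own observation channel
    (von Mises noise at ``spec.kappa_obs``) before inference.  Trials are
    grouped by set size and fitted batched.
    """
    rng = np.random.default_rng(seed)
    by_n = {}
    for idx, t in enumerate(dataset.trials):
        by_n.setdefault(t.set_size, []).append(idx)
    means = {}
    for n, idxs in sorted(by_n.items()):
        theta = np.stack([dataset.trials[i].presented for i in idxs])
        x = observe(theta, spec.kappa_obs, rng)
        k = spec.n_components or n
        s = _bfmm_gibbs_batch(
            x, spec.kappa_obs, k, spec.alpha, spec.mcmc.draws, spec.mcmc.tune, rng
        )
        per_draw = np.take_along_axis(s["mu"], s["z"].astype(np.int64), axis=2)
        agg = _circ_mean_axis(per_draw, axis=0)  # (T, n)
        for row, i in enumerate(idxs):
            means[i] = agg[row]
    return means


def build_bias_sample(dataset: SessionDataset, mean_kind="ensemble", model_spec=None,
                      anchor="presented", seed=None):
    """Per-report bias table for a dataset.

    Parameters
    ----------
    dataset : SessionDataset
    mean_kind : {"ensemble", "component"}
        "ensemble": distance to the circular mean of the trial's presented
        values.  "component": distance to the mean of the mixture component
        inferred to have generated each stimulus (requires ``model_spec``).
    model_spec : BFMMSpec, required for mean_kind="component".
    anchor : {"presented", "reported"}
        Whether distances are measured from the presented value (default) or
        the reported value.

    Returns
    -------
    (DataFrame, DataFrame)
        The bias table (one row per report of every included trial) and an
        exclusion log (trial_id, reason) for trials whose ensemble mean is
        undefined or set size is 1.
    """
    if mean_kind not in ("ensemble", "component"):
        raise ValueError("mean_kind must be 'ensemble' or 'component'")
    if anchor not in ("presented", "reported"):
        raise ValueError("anchor must be 'presented' or 'reported'")
    comp_means = None
    if mean_kind == "component":
        if not isinstance(model_spec, BFMMSpec):
            raise ValueError("component means require a BFMMSpec")
        comp_means = _component_means_for_dataset(dataset, model_spec, seed)

    frames, excluded = [], []
    for idx, t in enumerate(dataset.trials):
        if t.set_size < 2:
            excluded.append({"trial_id": t.trial_id, "reason": "set size 1"})
            continue
        if mean_kind == "ensemble":
            try:
                mean = np.full(t.set_size, ensemble_mean_of_trial(t))
            except ZeroResultantError:
                excluded.append({"trial_id": t.trial_id, "reason": "zero resultant"})
                continue
        else:
            mean = comp_means[idx]
        frame = bias_sample_from_arrays(
            t.presented[None, :],
            t.reported[None, :],
            mean[None, :],
            mean_kind=mean_kind,
            anchor=anchor,
            trial_ids=[t.trial_id],
        )
        frames.append(frame)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else bias_sample_from_arrays(np.empty((0, 1)), np.empty((0, 1)), np.empty(0))
    )
    return table, pd.DataFrame(excluded, columns=["trial_id", "reason"])


def _fit(frame, domain, report_order=None):
    lo, hi = domain
    sub = frame[(frame["distance_to_mean"] >= lo) & (frame["distance_to_mean"] <= hi)]
    if report_order is not None:
        sub = sub[sub["report_order"] == report_order]
    if len(sub) < 10:
        raise ValueError(
            f"need at least 10 in-domain rows, got {len(sub)}"
            + (f" for report order {report_order}" if report_order else "")
        )
    x = sm.add_constant(sub["distance_to_mean"].to_numpy())
    fit = sm.OLS(sub["error"].to_numpy(), x).fit()
    return BiasRegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n_used=int(fit.nobs),
        domain=tuple(domain),
        report_order=report_order,
    )


def bias_regression(sample: pd.DataFrame, by_report_order=False,
                    domain=(-DOMAIN_HALF_WIDTH, DOMAIN_HALF_WIDTH)):
    """Restricted-domain OLS of error on distance-to-mean.

    Returns a single :class:`BiasRegressionResult` collapsed across reports,
    or, with ``by_report_order``, a dict mapping report order -> result plus
    the collapsed result under the key ``"all"``.
    """
    if not by_report_order:
        return _fit(sample, domain)
    out = {"all": _fit(sample, domain)}
    for order in sorted(sample["report_order"].unique()):
        out[int(order)] = _fit(sample, domain, report_order=int(order))
    return out


def bias_function(sample: pd.DataFrame, n_bins=90) -> pd.DataFrame:
    """Binned bias function: mean and SD of error per distance bin.

    Equal-width bins over (-pi, pi]; empty bins are reported with NaN mean
    and SD (missing, not zero).
    """
    if len(sample) == 0:
        raise ValueError("empty bias sample")
    width = TWO_PI / n_bins
    edges = -np.pi + width * np.arange(n_bins + 1)
    centers = edges[:-1] + width / 2
    idx = np.clip(((sample["distance_to_mean"].to_numpy() + np.pi) / width).astype(int), 0,
                  n_bins - 1)
    err = sample["error"].to_numpy()
    rows = []
    for b in range(n_bins):
        vals = err[idx == b]
        rows.append(
            {
                "bin_center": centers[b],
                "n": vals.size,
                "mean_error": float(vals.mean()) if vals.size else np.nan,
                "sd_error": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
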