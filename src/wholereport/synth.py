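"""Synthetic whole-report datasets with known statistical structure.

Two simple observer models bracket the dependence analyses:

* the **independent observer** reports each stimulus through its own von
  Mises memory noise (plus an optional uniform guess process), with no
  interaction between reports — the null model under which within-trial
  relative distances are uniform;
* the **grouping observer** has the same marginal noise but chooses its
  report *order* by similarity, walking a greedy nearest-neighbour chain
  through its remembered values — the positive control that produces the
  consecutive-reports-cluster signature seen in human colour data.

Ensemble-model observers (hierarchical and mixture encoders) are available
through :mod:`wholereport.ensemble`; this module wraps their simulations into
the same dataset containers.

Stimulus sampling matches the experiments: the continuous task draws
i.i.d. uniformly from the 360-value grid, the discrete task draws without
replacement from the 8-value grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import KAPPA_CAP, circ_dist, snap_to_grid, wrap_angle
from .ensemble import BFMMSpec, HBMSpec, simulate_whole_report_trials
from .task import TASKS, SessionDataset, TrialRecord

__all__ = [
    "ObserverConfig",
    "sample_stimuli",
    "simulate_independent_observer",
    "simulate_grouping_observer",
    "simulate_ensemble_observer",
    "generate_benchmark_suite",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Configuration of a synthetic observer.

    Attributes
    ----------
    kind : {"independent", "grouping", "hbm", "bfmm"}
    kappa_report : float
        Concentration of the von Mises memory/report noise (>= 0).
    guess_rate : float
        Probability in [0, 1] that a report is a uniform grid guess.
    ordering : {"confidence", "random", "similarity_chain"}
        How report order is chosen.  "confidence" ranks reports by ascending
        realized noise magnitude (a metacognition-free stand-in for
        "report in order of confidence"); "similarity_chain" is forced for
        the grouping observer.
    seed : int
    """

    kind: str = "independent"
    kappa_report: float = 10.0
    guess_rate: float = 0.0
    ordering: str = "confidence"
    seed: int = 0
    model_spec: object = None  # HBMSpec/BFMMSpec for kind in {"hbm", "bfmm"}

    def __post_init__(self):
        if self.kind not in ("independent", "grouping", "hbm", "bfmm"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError("guess_rate must be in [0, 1]")
        if self.kappa_report < 0:
            raise ValueError("kappa_report must be >= 0")
        if self.ordering not in ("confidence", "random", "similarity_chain"):
            raise ValueError(f"unknown ordering {self.ordering!r}")


def sample_stimuli(task, set_size, n_trials, rng):
    """Sample presented-value arrays, shape (n_trials, set_size).

    Continuous task: i.i.d. uniform over the 360-value grid.  Discrete task:
    uniform without replacement from the 8-value grid (so set size 8 presents
    every colour exactly once).
    """
    cfg = TASKS[task] if isinstance(task, str) else task
    if set_size not in cfg.set_sizes:
        raise ValueError(f"set size {set_size} not allowed for the {cfg.name} task")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = cfg.grid
    if cfg.allow_repeats:
        idx = rng.integers(0, grid.m, size=(n_trials, set_size))
        return grid.values[idx]
    if set_size > grid.m:
        raise ValueError("set size exceeds the discrete grid size")
    rows = [rng.permutation(grid.m)[:set_size] for _ in range(n_trials)]
    return grid.values[np.asarray(rows)]


def _noisy_memory(stimuli, config, grid, rng):
    """Per-location remembered values and their realized noise magnitudes."""
    n_trials, n = stimuli.shape
    if config.kappa_report >= KAPPA_CAP:
        remembered = stimuli.copy()
    else:
        remembered = wrap_angle(
            stimuli + rng.vonmises(0.0, max(config.kappa_report, 1e-12), size=stimuli.shape)
        )
    if config.guess_rate > 0:
        guess = rng.random(stimuli.shape) < config.guess_rate
        remembered = np.where(guess, grid.values[rng.integers(0, grid.m, stimuli.shape)], remembered)
    noise = np.abs(circ_dist(remembered, stimuli))
    return remembered, noise


def _order_for(config, noise, rng):
    if config.ordering == "confidence":
        return np.argsort(noise, kind="stable")
    return rng.permutation(noise.size)


def _condition_label(ordering):
    return "randomly_ordered" if ordering == "random" else "participant_ordered"


def _build_session(task_cfg, trials, participant_id, condition):
    return SessionDataset(
        participant_id=participant_id, task=task_cfg.name, trials=trials, condition=condition
    ).validate()


def simulate_independent_observer(stimuli, config: ObserverConfig, task="continuous",
                                  participant_id="sim"):
    """Whole-report dataset from the independence null model.

    Each report is the remembered value of its own location snapped to the
    response grid (or a uniform grid guess), mutually independent given the
    stimuli.  Report order carries no information about the values beyond the
    confidence ranking of each location's own noise.
    """
    if config.kind != "independent":
        raise ValueError("config.kind must be 'independent'")
    task_cfg = TASKS[task] if isinstance(task, str) else task
    rng = np.random.default_rng(config.seed)
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    grid = task_cfg.grid
    remembered, noise = _noisy_memory(stimuli, config, grid, rng)
    condition = _condition_label(config.ordering)
    trials = []
    for t in range(stimuli.shape[0]):
        order = _order_for(config, noise[t], rng)
        reports = snap_to_grid(remembered[t, order], grid)
        trials.append(
            TrialRecord(
                trial_id=t,
                set_size=stimuli.shape[1],
                presented=stimuli[t, order],
                reported=reports,
                locations=order,
                condition=condition,
            )
        )
    return _build_session(task_cfg, trials, participant_id, condition)


def _snap_no_repeat(value, grid, used):
    """Nearest grid value whose index is not in ``used`` (discrete reports
    never repeat a previously reported colour)."""
    d = np.abs(circ_dist(value, grid.values))
    d[list(used)] = np.inf
    return int(np.argmin(d))


def simulate_grouping_observer(stimuli, config: ObserverConfig, task="continuous",
                               participant_id="sim"):
    """Whole-report dataset from the similarity-grouping observer.

    Memory noise is identical to the independent observer, but the report
    order is a greedy nearest-neighbour chain through the remembered values:
    the first report is the most confident location, each later report is the
    closest not-yet-reported remembered value.  On the discrete task a
    previously reported colour is never repeated (the nearest unused button
    is pressed instead).
    """
    if config.kind != "grouping":
        raise ValueError("config.kind must be 'grouping'")
    task_cfg = TASKS[task] if isinstance(task, str) else task
    rng = np.random.default_rng(config.seed)
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    grid = task_cfg.grid
    remembered, noise = _noisy_memory(stimuli, config, grid, rng)
    condition = "participant_ordered"
    trials = []
    n = stimuli.shape[1]
    for t in range(stimuli.shape[0]):
        remaining = list(range(n))
        current = int(np.argmin(noise[t]))
        chain = [current]
        remaining.remove(current)
        while remaining:
            d = [abs(circ_dist(remembered[t, j], remembered[t, current])) for j in remaining]
            current = remaining[int(np.argmin(d))]
            chain.append(current)
            remaining.remove(current)
        order = np.asarray(chain)
        if task_cfg.allow_repeats:
            reports = snap_to_grid(remembered[t, order], grid)
        else:
            used, idxs = set(), []
            for j in order:
                k = _snap_no_repeat(remembered[t, j], grid, used)
                used.add(k)
                idxs.append(k)
            reports = grid.values[np.asarray(idxs)]
        trials.append(
            TrialRecord(
                trial_id=t,
                set_size=n,
                presented=stimuli[t, order],
                reported=np.atleast_1d(reports),
                locations=order,
                condition=condition,
            )
        )
    return _build_session(task_cfg, trials, participant_id, condition)


def simulate_ensemble_observer(stimuli, config: ObserverConfig, task="continuous",
                               participant_id="sim"):
    """Whole-report dataset from a hierarchical ensemble encoder (observe ->
    posterior -> mode -> snap), wrapped into a SessionDataset.  Report order
    is random (the encoders have no sequential component)."""
    if config.kind not in ("hbm", "bfmm"):
        raise ValueError("config.kind must be 'hbm' or 'bfmm'")
    spec = config.model_spec
    if spec is None or not isinstance(spec, (HBMSpec, BFMMSpec)):
        raise ValueError("config.model_spec must be an HBMSpec or BFMMSpec")
    task_cfg = TASKS[task] if isinstance(task, str) else task
    rng = np.random.default_rng(config.seed)
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    sim = simulate_whole_report_trials(stimuli, task_cfg.grid, spec, seed=rng)
    condition = "randomly_ordered"
    trials = []
    for t in range(stimuli.shape[0]):
        order = rng.permutation(stimuli.shape[1])
        trials.append(
            TrialRecord(
                trial_id=t,
                set_size=stimuli.shape[1],
                presented=stimuli[t, order],
                reported=sim.reported[t, order],
                locations=order,
                condition=condition,
            )
        )
    return _build_session(task_cfg, trials, participant_id, condition)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Declarative description of a benchmark collection."""

    tasks: tuple = ("continuous", "discrete")
    observers: tuple = ("independent", "grouping")
    orderings: tuple = ("confidence", "random")
    n_trials: int = 100
    kappa_report: float = 10.0
    guess_rate: float = 0.1
    seed: int = 0


def generate_benchmark_suite(config: BenchmarkConfig = BenchmarkConfig()):
    """Deterministic collection of datasets covering tasks x orderings x
    observers x all allowed set sizes (plus the set-size-one continuous
    dataset used for observation-noise fitting).

    Returns a dict keyed by ``(task, observer, ordering, set_size)``.
    """
    suite = {}
    counter = 0
    for task in config.tasks:
        cfg = TASKS[task]
        for observer in config.observers:
            orderings = ("similarity_chain",) if observer == "grouping" else config.orderings
            for ordering in orderings:
                for set_size in cfg.set_sizes:
                    counter += 1
                    seed = np.random.SeedSequence([config.seed, counter]).generate_state(1)[0]
                    seed = int(seed % (2**31))
                    stim = sample_stimuli(task, set_size, config.n_trials,
                                          np.random.default_rng(seed))
                    obs_cfg = ObserverConfig(
                        kind=observer,
                        kappa_report=config.kappa_report,
                        guess_rate=config.guess_rate,
                        ordering=ordering,
                        seed=seed + 1,
                    )
                    pid = f"{task[:4]}-{observer[:5]}-{ordering[:4]}-N{set_size}"
                    if observer == "independent":
                        ds = simulate_independent_observer(stim, obs_cfg, task, pid)
                    else:
                        ds = simulate_grouping_observer(stim, obs_cfg, task, pid)
                    suite[(task, observer, ordering, set_size)] = ds
    return suite
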