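"""Data model and CSV I/O for whole-report experiments.

A whole-report trial presents N stimuli simultaneously and then probes every
display location, so each trial yields N (presented, reported) pairs plus the
order in which the participant produced them.  Two task variants are
supported: the *continuous* task (360-value colour wheel; set sizes 1, 2, 3,
4, 6) and the *discrete* task (8 response buttons; set sizes 2, 3, 4, 6, 8,
no stimulus value repeats within a trial).

On disk, datasets are long-format CSV with one row per report and angles in
integer degrees; in memory everything is wrapped radians.  Columns::

    participant, task, condition, feature, set_size, trial,
    report_order, location, presented_deg, reported_deg

``presented_deg`` on each row is the value shown at the display location that
this report probed, so report errors are computed per location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import StimulusGrid, circ_dist, wrap_angle

__all__ = [
    "CSV_COLUMNS",
    "TASKS",
    "TaskConfig",
    "TrialRecord",
    "SessionDataset",
    "TrialValidationError",
    "MissingColumnError",
    "OffGridError",
    "DuplicateReportError",
    "read_trials",
    "write_trials",
    "pooled_error_table",
]

CSV_COLUMNS = [
    "participant",
    "task",
    "condition",
    "feature",
    "set_size",
    "trial",
    "report_order",
    "location",
    "presented_deg",
    "reported_deg",
]

CONDITIONS = ("participant_ordered", "randomly_ordered")
FEATURES = ("color", "orientation")


class TrialValidationError(ValueError):
    """Base class for dataset validation failures."""


class MissingColumnError(TrialValidationError):
    pass


class OffGridError(TrialValidationError):
    pass


class DuplicateReportError(TrialValidationError):
    pass


@dataclass(frozen=True)
class TaskConfig:
    """Static description of a task variant: grid size and allowed set sizes."""

    name: str
    grid_size: int
    set_sizes: tuple

    @property
    def grid(self) -> StimulusGrid:
        return StimulusGrid(self.grid_size)

    @property
    def allow_repeats(self) -> bool:
        # Discrete trials never repeat a stimulus value; the continuous task
        # samples 360 values with replacement (repeats are possible but rare).
        return self.name == "continuous"


TASKS = {
    "continuous": TaskConfig("continuous", 360, (1, 2, 3, 4, 6)),
    "discrete": TaskConfig("discrete", 8, (2, 3, 4, 6, 8)),
}


@dataclass
class TrialRecord:
    """One whole-report trial, indexed by report position.

    ``presented[j]``, ``reported[j]`` and ``locations[j]`` describe the j-th
    report the participant made (0-based internally; 1-based in files):
    the display location probed, the stimulus value that had been shown
    there, and the value reported for it.
    """

    trial_id: int
    set_size: int
    presented: np.ndarray
    reported: np.ndarray
    locations: np.ndarray
    condition: str = "participant_ordered"
    feature: str = "color"

    def __post_init__(self):
        self.presented = wrap_angle(np.asarray(self.presented, dtype=float))
        self.reported = wrap_angle(np.asarray(self.reported, dtype=float))
        self.locations = np.asarray(self.locations, dtype=int)

    def validate(self, task: TaskConfig):
        n = self.set_size
        if not (len(self.presented) == len(self.reported) == len(self.locations) == n):
            raise TrialValidationError(
                f"trial {self.trial_id}: expected {n} reports, got "
                f"{len(self.presented)}/{len(self.reported)}/{len(self.locations)}"
            )
        if n not in task.set_sizes:
            raise TrialValidationError(
                f"trial {self.trial_id}: set size {n} not allowed for the {task.name} task"
            )
        if sorted(self.locations.tolist()) != list(range(n)):
            raise TrialValidationError(
                f"trial {self.trial_id}: locations must be a permutation of 0..{n - 1}"
            )
        grid = task.grid
        for label, vals in (("presented", self.presented), ("reported", self.reported)):
            if not all(grid.contains(v) for v in np.atleast_1d(vals)):
                raise OffGridError(
                    f"trial {self.trial_id}: {label} value off the {task.name} grid"
                )
        if not task.allow_repeats:
            if len(set(np.round(self.presented, 9).tolist())) != n:
                raise TrialValidationError(
                    f"trial {self.trial_id}: repeated presented value in discrete task"
                )

    def errors(self):
        """Signed report errors, ``circ_dist(reported, presented)``, by report position."""
        return circ_dist(self.reported, self.presented)


@dataclass
class SessionDataset:
    """All trials of one participant in one task/condition."""

    participant_id: str
    task: str
    trials: list = field(default_factory=list)
    condition: str = "participant_ordered"

    def __post_init__(self):
        if self.task not in TASKS:
            raise TrialValidationError(f"unknown task {self.task!r}")

    @property
    def task_config(self) -> TaskConfig:
        return TASKS[self.task]

    @property
    def grid(self) -> StimulusGrid:
        return self.task_config.grid

    def validate(self):
        for t in self.trials:
            t.validate(self.task_config)
        return self

    def set_sizes(self):
        return sorted({t.set_size for t in self.trials})

    def __len__(self):
        return len(self.trials)


def _to_degrees(x):
    deg = np.degrees(np.mod(np.asarray(x, dtype=float), 2 * np.pi))
    rounded = np.rint(deg)
    return np.where(np.abs(deg - rounded) < 1e-6, rounded, deg)


def write_trials(dataset: SessionDataset, path):
    """Write a dataset to CSV in the documented dialect.

    Rows are ordered by (trial, report_order); angles are degrees in [0, 360).
    """
    rows = []
    for t in sorted(dataset.trials, key=lambda t: t.trial_id):
        pres = _to_degrees(t.presented)
        rep = _to_degrees(t.reported)
        for j in range(t.set_size):
            rows.append(
                {
                    "participant": dataset.participant_id,
                    "task": dataset.task,
                    "condition": t.condition,
                    "feature": t.feature,
                    "set_size": t.set_size,
                    "trial": t.trial_id,
                    "report_order": j + 1,
                    "location": int(t.locations[j]),
                    "presented_deg": pres[j],
                    "reported_deg": rep[j],
                }
            )
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    for col in ("presented_deg", "reported_deg"):
        if len(frame) and np.allclose(frame[col], np.rint(frame[col])):
            frame[col] = frame[col].astype(int)
    frame.to_csv(path, index=False)
    return path


def read_trials(path, task_config=None) -> SessionDataset:
    """Read one participant's whole-report CSV into a validated dataset.

    Parameters
    ----------
    path : str or Path
        CSV file in the documented dialect.
    task_config : TaskConfig, optional
        Expected task variant; defaults to the ``task`` column's value.

    Raises
    ------
    MissingColumnError, OffGridError, DuplicateReportError, TrialValidationError
        Each names the offending column or row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise TrialValidationError(f"{path}: no data rows")
    participants = frame["participant"].unique()
    if len(participants) != 1:
        raise TrialValidationError(
            f"{path}: expected a single participant, found {list(participants)}"
        )
    tasks = frame["task"].unique()
    if len(tasks) != 1 or tasks[0] not in TASKS:
        raise TrialValidationError(f"{path}: expected a single known task, found {list(tasks)}")
    task = task_config or TASKS[tasks[0]]
    if tasks[0] != task.name:
        raise TrialValidationError(f"{path}: task column {tasks[0]!r} != expected {task.name!r}")

    dup = frame.duplicated(subset=["trial", "report_order"])
    if dup.any():
        row = frame.index[dup][0]
        raise DuplicateReportError(
            f"{path}: duplicate (trial, report_order) at row {row + 2} "
            f"(trial={frame.loc[row, 'trial']}, report_order={frame.loc[row, 'report_order']})"
        )

    step = 360.0 / task.grid_size
    for col in ("presented_deg", "reported_deg"):
        off = ~np.isclose(np.mod(frame[col].to_numpy(float), step), 0.0) & ~np.isclose(
            np.mod(frame[col].to_numpy(float), step), step
        )
        if off.any():
            row = int(np.flatnonzero(off)[0])
            raise OffGridError(
                f"{path}: {col}={frame.loc[row, col]} at row {row + 2} is off the "
                f"{task.name} grid (multiples of {step:g} deg)"
            )

    trials = []
    condition = None
    for trial_id, g in frame.groupby("trial", sort=True):
        g = g.sort_values("report_order")
        n = int(g["set_size"].iloc[0])
        if sorted(g["report_order"].tolist()) != list(range(1, n + 1)):
            raise TrialValidationError(
                f"{path}: trial {trial_id}: report_order must be a permutation of 1..{n}"
            )
        rec = TrialRecord(
            trial_id=int(trial_id),
            set_size=n,
            presented=np.radians(g["presented_deg"].to_numpy(float)),
            reported=np.radians(g["reported_deg"].to_numpy(float)),
            locations=g["location"].to_numpy(int),
            condition=str(g["condition"].iloc[0]),
            feature=str(g["feature"].iloc[0]),
        )
        condition = rec.condition
        trials.append(rec)

    return SessionDataset(
        participant_id=str(participants[0]),
        task=task.name,
        trials=trials,
        condition=condition or "participant_ordered",
    ).validate()


def pooled_error_table(dataset: SessionDataset) -> pd.DataFrame:
    """One row per report: (trial, set_size, report_order, location, error).

    The error is the signed circular distance between the reported value and
    the value presented at the probed location; row count equals the total
    number of reports in the dataset.
    """
    rows = []
    for t in dataset.trials:
        errs = t.errors()
        for j in range(t.set_size):
            rows.append(
                (t.trial_id, t.set_size, j + 1, int(t.locations[j]), float(errs[j]))
            )
    return pd.DataFrame(
        rows, columns=["trial", "set_size", "report_order", "location", "error"]
    )
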