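"""Shared data model: trial tables, neural epochs, and study configuration.

Trials are carried as a pandas DataFrame (the "trial table") with one row
per trial and documented columns; :class:`TrialRecord` gives the same
fields as a typed record for single-trial use.  Binned spike counts live
in :class:`NeuralEpoch`.

Conventions
-----------
* colors are radians in [0, 2pi); the stimulus grid is 64 uniform points
* cue c = 1 means the upper color is the target, c = 0 the lower
* the target color t and distractor d are derived from (u, l, c)
* task_type "single" trials carry exactly one stimulus and no distractor
* time bins are half-open [a, b) in seconds relative to a named event
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .circular import wrap_to_2pi

TRIAL_COLUMNS = [
    "session_id",
    "trial_id",
    "task_type",
    "u",
    "l",
    "c",
    "c_report",
    "response_time",
]

TASK_TYPES = ("retro", "pro", "single")
ALIGNMENT_EVENTS = ("stimuli_on", "cue_on", "wheel_on")


class SchemaError(ValueError):
    """A required column/group is missing or malformed."""


class AlignmentError(ValueError):
    """Trial counts disagree between behavioral and neural containers."""


@dataclass
class TrialRecord:
    """One trial's stimuli, cue, and report (angles in radians, [0, 2pi))."""

    trial_id: int
    task_type: str
    u: Optional[float]
    l: Optional[float]
    c: int
    c_report: float
    session_id: str = "s0"
    response_time: Optional[float] = None

    @property
    def t(self) -> float:
        """Target color: u if the upper stimulus is cued (c=1), else l."""
        return self.u if self.c == 1 else self.l

    @property
    def d(self) -> Optional[float]:
        """Distractor color (None on single-stimulus trials)."""
        return self.l if self.c == 1 else self.u


def derive_target_distractor(trials: pd.DataFrame) -> pd.DataFrame:
    """Populate derived columns ``t`` and ``d`` from (u, l, c).

    On single-stimulus trials the absent color is NaN and ``d`` is NaN.
    """
    trials = trials.copy()
    c = trials["c"].to_numpy()
    u = trials["u"].to_numpy(dtype=float)
    l = trials["l"].to_numpy(dtype=float)
    trials["t"] = np.where(c == 1, u, l)
    trials["d"] = np.where(c == 1, l, u)
    return trials


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table, wrap angles into [0, 2pi) and derive t, d."""
    missing = [col for col in TRIAL_COLUMNS if col not in trials.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {missing}")
    bad = set(trials["task_type"].unique()) - set(TASK_TYPES)
    if bad:
        raise SchemaError(f"unknown task_type value(s): {sorted(bad)}")
    if not trials["c"].isin([0, 1]).all():
        raise SchemaError("cue column c must be binary (0=lower, 1=upper)")

    trials = trials.copy()
    for col in ("u", "l", "c_report"):
        vals = trials[col].to_numpy(dtype=float)
        ok = np.isnan(vals)
        vals = np.where(ok, np.nan, wrap_to_2pi(vals))
        trials[col] = vals

    single = trials["task_type"] == "single"
    n_colors = (~trials.loc[single, ["u", "l"]].isna()).sum(axis=1)
    if single.any() and not (n_colors == 1).all():
        raise SchemaError("single-task trials must carry exactly one stimulus")
    both = ~single
    if both.any() and trials.loc[both, ["u", "l"]].isna().any().any():
        raise SchemaError("two-stimulus trials must carry both u and l")
    # a single trial's sole stimulus must sit in the cued role
    if single.any():
        c1 = single & (trials["c"] == 1)
        c0 = single & (trials["c"] == 0)
        if trials.loc[c1, "u"].isna().any() or trials.loc[c0, "l"].isna().any():
            raise SchemaError("single-task stimulus must occupy the cued location")
    return derive_target_distractor(trials)


def trials_to_records(trials: pd.DataFrame) -> list[TrialRecord]:
    """Convert a validated trial table to a list of TrialRecords."""
    records = []
    for row in trials.itertuples(index=False):
        records.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                task_type=row.task_type,
                u=None if pd.isna(row.u) else float(row.u),
                l=None if pd.isna(row.l) else float(row.l),
                c=int(row.c),
                c_report=float(row.c_report),
                session_id=str(row.session_id),
                response_time=None if pd.isna(row.response_time) else float(row.response_time),
            )
        )
    return records


@dataclass
class NeuralEpoch:
    """Binned spike counts for one epoch of one session.

    counts has shape (trials, units, bins); bin_edges are seconds relative
    to ``alignment_event`` with uniform width and half-open bins [a, b).
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    alignment_event: str
    unit_ids: list[str] = field(default_factory=list)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.ndim != 3:
            raise SchemaError("counts must be (trials, units, bins)")
        if self.alignment_event not in ALIGNMENT_EVENTS:
            raise SchemaError(f"unknown alignment_event {self.alignment_event!r}")
        if len(self.bin_edges) != self.counts.shape[2] + 1:
            raise SchemaError("bin_edges must have one more entry than bins")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise SchemaError("bin widths must be uniform within an epoch")
        if np.any(self.counts < 0):
            raise SchemaError("spike counts must be nonnegative")
        if not self.unit_ids:
            self.unit_ids = [f"u{i:03d}" for i in range(self.counts.shape[1])]
        if not self.region_labels:
            self.region_labels = ["unknown"] * self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def summed(self) -> np.ndarray:
        """Total counts per trial and unit (summed over time bins)."""
        return self.counts.sum(axis=2)


@dataclass
class StudyConfig:
    """Analysis configuration mirroring the study's fixed choices.

    Defaults follow the published analysis: K=5 linear periodic splines,
    95% PCA variance, 500 ms windows, decoding thresholds
    (p_correct > 0.6, p_swap > 0.4), projection thresholds
    (p_correct > 0.3, p_swap > 0.3), and a pi/4 minimum color separation
    for the cross-validated projection analysis.
    """

    spline_knots: int = 5
    spline_order: int = 1
    p_correct_decode: float = 0.6
    p_swap_decode: float = 0.4
    p_correct_proj: float = 0.3
    p_swap_proj: float = 0.3
    color_separation_min: float = np.pi / 4
    pca_variance: float = 0.95
    mcmc_chains: int = 4
    mcmc_warmup: int = 500
    mcmc_samples: int = 500
    mcmc_seed: int = 0
    window_width: float = 0.5
    window_step: float = 0.05
    ridge_lambda: float = 1.0
    exclusion_block: int = 50
    knn_k: int = 5
    max_pca_dims: Optional[int] = None

    def __post_init__(self):
        for name in ("p_correct_decode", "p_swap_decode", "p_correct_proj", "p_swap_proj"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")
        if self.spline_knots < 3:
            raise ValueError("spline_knots must be >= 3")

    @property
    def basis(self):
        from .splines import SplineBasisSpec

        return SplineBasisSpec(self.spline_knots, self.spline_order)
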