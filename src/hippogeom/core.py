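"""Core data containers shared across the pipeline.

A recording session is represented as a set of frame-aligned trajectories
(self avatar, chosen/unchosen prey, predator, gaze), a frames x neurons
spike-count matrix, and a trial table.  All positions are in screen pixels
with the origin at the bottom-left corner, x rightward and y upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical spatial variables, in pipeline order
VARIABLES = ("self", "chosen_prey", "unchosen_prey", "predator", "gaze")

TRIAL_COLUMNS = (
    "trial_id",
    "start_frame",
    "end_frame",
    "outcome",
    "chosen_prey_id",
    "reward",
)

OUTCOMES = ("captured", "timeout", "caught_by_predator")


@dataclass
class Trajectory:
    """Frame-aligned 2-D track of one spatial variable.

    ``valid`` marks frames where the position is defined: gaze drops out when
    tracking fails, the predator is absent on predator-free trials, and
    inter-trial gaps are invalid for every variable.
    """

    variable_id: str
    frames: np.ndarray  # (T,) int
    t: np.ndarray  # (T,) seconds
    x: np.ndarray  # (T,) px, NaN where invalid
    y: np.ndarray  # (T,) px, NaN where invalid
    valid: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        n = len(self.frames)
        for name in ("t", "x", "y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"Trajectory field {name!r} length mismatch")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SpikeMatrix:
    """Binned spike counts, frames x neurons."""

    counts: np.ndarray  # (T, N) nonnegative int
    frame_dt: float  # s

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (frames x neurons)")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("spike counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]


@dataclass
class Session:
    """One synchronized recording session.

    trajectories: variable -> Trajectory, all of equal frame length.
    trials: DataFrame with TRIAL_COLUMNS; frame ranges are inclusive of
    start_frame and exclusive of end_frame.
    """

    trajectories: dict[str, Trajectory]
    trials: pd.DataFrame
    spikes: SpikeMatrix | None = None
    frame_dt: float = 1.0 / 60.0
    field_size: tuple[float, float] = (1800.0, 1000.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(tr) for tr in self.trajectories.values()}
        if len(lengths) > 1:
            raise ValueError(f"trajectory lengths differ: {sorted(lengths)}")
        if self.spikes is not None and lengths:
            if self.spikes.n_frames != lengths.pop():
                raise ValueError("spike matrix frame count does not match trajectories")

    @property
    def n_frames(self) -> int:
        if not self.trajectories:
            return 0
        return len(next(iter(self.trajectories.values())))

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.trajectories)

    def trial_mask(self, outcome: str | None = "captured") -> np.ndarray:
        """Boolean mask over frames belonging to trials with ``outcome``.

        ``outcome=None`` keeps every trial.
        """
        mask = np.zeros(self.n_frames, dtype=bool)
        rows = self.trials
        if outcome is not None:
            rows = rows[rows["outcome"] == outcome]
        for _, row in rows.iterrows():
            mask[int(row["start_frame"]) : int(row["end_frame"])] = True
        return mask


def make_trials_frame(records: list[dict]) -> pd.DataFrame:
    """Build and validate a trial table from per-trial dicts."""
    df = pd.DataFrame(records, columns=list(TRIAL_COLUMNS))
    if len(df):
        if (df["start_frame"] >= df["end_frame"]).any():
            raise ValueError("trial with start_frame >= end_frame")
        bad = ~df["outcome"].isin(OUTCOMES)
        if bad.any():
            raise ValueError(f"unknown outcome(s): {df.loc[bad, 'outcome'].unique()}")
    return df
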