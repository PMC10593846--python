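"""Shared in-memory containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Recording", "EventTable", "StateTimeCourse", "VALID_CONDITIONS"]

VALID_CONDITIONS = frozenset({"0T", "0D", "1T", "1D", "2T", "2D"})


@dataclass
class Recording:
    """A parcellated multichannel recording: regions x samples at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    region_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (regions x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("Recording.data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.region_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_names)} region names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


class EventTable:
    """Stimulus onsets with condition labels (0/1/2-back x target/distractor).

    Thin wrapper over a DataFrame with columns ``onset_s`` (seconds),
    ``condition`` (one of 0T, 0D, 1T, 1D, 2T, 2D) and ``block``.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"onset_s", "condition", "block"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"EventTable missing columns: {sorted(missing)}")
        bad = ~frame["condition"].isin(VALID_CONDITIONS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown condition label {frame['condition'].iloc[row]!r} "
                f"at row {row}"
            )
        if (frame["onset_s"] < 0).any():
            raise ValueError("negative onset in EventTable")
        self.frame = frame.reset_index(drop=True)

    @property
    def onsets_s(self) -> np.ndarray:
        return self.frame["onset_s"].to_numpy(dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def n_targets(self, load: int) -> int:
        return int((self.frame["condition"] == f"{load}T").sum())


@dataclass
class StateTimeCourse:
    """Per-sample posterior state probabilities (the HMM "gamma").

    ``gamma`` is samples x K with rows on the simplex; ``xi`` holds the
    summed pairwise transition posteriors (K x K).  ``subject_boundaries``
    gives the start index of each subject's segment in the concatenated
    sample axis; ``sample_indices`` maps each gamma row back to the original
    (pre-embedding) sample index of its subject, so event onsets can be
    aligned after edge trimming.
    """

    gamma: np.ndarray
    xi: np.ndarray | None = None
    subject_boundaries: np.ndarray | None = None
    sample_indices: np.ndarray | None = None
    log_likelihood: float | None = None
    free_energy_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2:
            raise ValueError("gamma must be samples x K")
        rows = self.gamma.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("gamma rows must sum to 1")
        if (self.gamma < -1e-12).any() or (self.gamma > 1 + 1e-12).any():
            raise ValueError("gamma entries must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.gamma.shape[1]

    @property
    def n_samples(self) -> int:
        return self.gamma.shape[0]

    def hard_path(self) -> np.ndarray:
        return np.argmax(self.gamma, axis=1)
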