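"""Temporal characterization of state time courses.

Fractional occupancy, lifetimes, and interval times summarize how often and
for how long each network state is visited; event-locked epoching with
pre-stimulus baseline correction turns the state probabilities into trialwise
task-evoked occupancy curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EventTable, StateTimeCourse

__all__ = ["TemporalStats", "EpochedCourse", "temporal_stats", "epoch_and_baseline"]


@dataclass
class TemporalStats:
    """Per-state temporal summaries.

    ``fo`` (fractional occupancy) partitions the samples, so it sums to 1;
    ``lt_ms`` is the mean contiguous-visit duration and ``it_ms`` the mean
    gap between consecutive visits, both in milliseconds.  A state that is
    never visited (or visited once) has NaN where the quantity is undefined.
    """

    fo: np.ndarray
    lt_ms: np.ndarray
    it_ms: np.ndarray
    lifetimes_ms: list[np.ndarray]
    intervals_ms: list[np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": np.arange(self.fo.size),
                "FO": self.fo,
                "LT_ms": self.lt_ms,
                "IT_ms": self.it_ms,
            }
        )


@dataclass
class EpochedCourse:
    """Baseline-corrected trials x timepoints x states occupancy.

    ``times_s`` is relative to stimulus onset; ``conditions`` labels each
    kept trial; ``n_dropped`` counts trials whose window fell outside the
    recording (after edge trimming).
    """

    data: np.ndarray
    times_s: np.ndarray
    conditions: np.ndarray
    n_dropped: int

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _runs(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) indices of True runs."""
    padded = np.concatenate(([False], binary, [False]))
    diff = np.diff(padded.astype(np.int8))
    return np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)


def temporal_stats(
    course: StateTimeCourse | np.ndarray,
    fs: float,
    gamma_threshold: float | None = None,
) -> TemporalStats:
    """Compute FO/LT/IT from a state time course.

    The course is binarized by per-sample argmax of gamma (so occupancy is a
    partition); pass ``gamma_threshold`` to instead mark a state active
    wherever its probability exceeds the threshold (occupancies then need not
    sum to 1 and are reported as raw fractions).
    """
    if isinstance(course, StateTimeCourse):
        gamma = course.gamma
        k = course.n_states
    else:
        gamma = np.asarray(course)
        if gamma.ndim == 1:  # hard path
            k = int(gamma.max()) + 1
            gamma = np.eye(k)[gamma.astype(int)]
        k = gamma.shape[1]
    n = gamma.shape[0]
    period_ms = 1000.0 / fs

    if gamma_threshold is None:
        hard = np.argmax(gamma, axis=1)
        active = np.eye(k, dtype=bool)[hard].T  # (K, n)
    else:
        active = (gamma > gamma_threshold).T

    fo = active.sum(axis=1) / n
    lt = np.full(k, np.nan)
    it = np.full(k, np.nan)
    lifetimes, intervals = [], []
    for s in range(k):
        starts, stops = _runs(active[s])
        lts = (stops - starts) * period_ms
        lifetimes.append(lts)
        if lts.size:
            lt[s] = lts.mean()
        if starts.size >= 2:
            gaps = (starts[1:] - stops[:-1]) * period_ms
            intervals.append(gaps)
            it[s] = gaps.mean()
        else:
            intervals.append(np.empty(0))
    return TemporalStats(fo=fo, lt_ms=lt, it_ms=it,
                         lifetimes_ms=lifetimes, intervals_ms=intervals)


def epoch_and_baseline(
    course: StateTimeCourse,
    events: EventTable,
    fs: float,
    window_s: tuple[float, float] = (-0.2, 1.2),
    baseline_s: tuple[float, float] = (-0.2, -0.03),
) -> EpochedCourse:
    """Epoch gamma around stimulus onsets and subtract the pre-stimulus mean.

    The default window is [-0.2, 1.2] s (351 samples at 250 Hz) with the
    baseline over [-200, -30] ms.  Onsets are mapped through the embedding's
    surviving-sample index map (``course.sample_indices``) when present, so
    edge trimming cannot misalign latencies; trials whose window is not fully
    inside the course are dropped and counted.
    """
    gamma = course.gamma
    n, k = gamma.shape
    lo = int(round(window_s[0] * fs))
    hi = int(round(window_s[1] * fs))
    offsets = np.arange(lo, hi + 1)
    times_s = offsets / fs
    # inclusive nearest-sample baseline window
    bmask = (offsets >= np.round(baseline_s[0] * fs)) & (
        offsets <= np.round(baseline_s[1] * fs)
    )
    if not bmask.any():
        raise ValueError("baseline window contains no samples")

    if course.sample_indices is not None:
        idx = np.asarray(course.sample_indices)
        start_orig = int(idx[0])  # contiguous surviving block
        if not np.array_equal(idx, np.arange(start_orig, start_orig + n)):
            raise ValueError("sample index map must be contiguous")
    else:
        start_orig = 0

    trials, kept_cond = [], []
    dropped = 0
    for onset, cond in zip(events.onsets_s, events.conditions):
        center = int(round(onset * fs)) - start_orig
        sel = center + offsets
        if sel[0] < 0 or sel[-1] >= n:
            dropped += 1
            continue
        seg = gamma[sel]
        seg = seg - seg[bmask].mean(axis=0, keepdims=True)
        trials.append(seg)
        kept_cond.append(cond)
    data = (
        np.asarray(trials)
        if trials
        else np.empty((0, offsets.size, k))
    )
    return EpochedCourse(
        data=data,
        times_s=times_s,
        conditions=np.asarray(kept_cond, dtype=object),
        n_dropped=dropped,
    )
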