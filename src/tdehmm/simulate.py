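"""Ground-truthed simulation of Markov-switching oscillatory network recordings.

The generator emulates parcellated, leakage-orthogonalized source-space
recordings whose dynamics follow a sticky Markov chain over K hidden network
states.  Each state is a frequency-specific oscillatory network: a subset of
regions carries a sinusoid at the state's centre frequency (with optional
per-region phase lags), all regions carry additive white noise.  A companion
event generator reproduces the blockwise n-back task structure (12 blocks of
20 letters, 4 blocks per load condition) so that event-locked modulation of
state probability can be injected and later recovered.

Everything returned is ground truth: the exact transition matrices used, the
sampled state path, and the per-state spectral signature, so that every
downstream inference stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import EventTable, Recording

__all__ = [
    "StateSpec",
    "SimConfig",
    "TaskConfig",
    "GroundTruth",
    "simulate_state_path",
    "render_recording",
    "simulate_task_events",
    "CONDITION_LABELS",
]

#: condition labels: working-memory load (0/1/2-back) x target (T) / distractor (D)
CONDITION_LABELS = ("0T", "0D", "1T", "1D", "2T", "2D")


class InvalidConfigError(ValueError):
    """Raised when a simulation or task configuration violates an invariant."""


@dataclass(frozen=True)
class StateSpec:
    """Oscillatory network signature of one hidden state.

    Parameters
    ----------
    regions
        Indices of the regions participating in the network.
    freq_hz
        Centre frequency of the state's oscillation.
    amplitude
        Oscillation amplitude; scalar (shared) or one value per region.
    lags_s
        Per-region phase lag in seconds (same length as ``regions``);
        pairwise lag between two regions is the difference of their entries.
        Zero (default) gives instantaneous (zero-lag) coupling.
    """

    regions: tuple[int, ...]
    freq_hz: float
    amplitude: float | tuple[float, ...] = 1.0
    lags_s: tuple[float, ...] | None = None

    def amplitudes(self) -> np.ndarray:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.ndim == 0:
            amp = np.full(len(self.regions), float(amp))
        return amp

    def lags(self) -> np.ndarray:
        if self.lags_s is None:
            return np.zeros(len(self.regions))
        return np.asarray(self.lags_s, dtype=float)


def _default_state_specs(n_states: int, n_regions: int) -> tuple[StateSpec, ...]:
    # Disjoint region subsets, frequencies spread over the 4-25 Hz range the
    # analysis targets (theta / alpha / beta style networks).
    freqs = np.linspace(5.0, 25.0, n_states)
    per = max(2, n_regions // n_states)
    specs = []
    for k in range(n_states):
        lo = (k * per) % n_regions
        regions = tuple(sorted({(lo + i) % n_regions for i in range(per)}))
        specs.append(StateSpec(regions=regions, freq_hz=float(freqs[k])))
    return tuple(specs)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the Markov-switching oscillatory simulator.

    Defaults mirror the recording setup the analysis expects: 42 cortical
    regions at 250 Hz with 6 hidden states whose ~70 ms lifetimes correspond
    to a self-transition probability near 0.95 per 4 ms sample.
    """

    n_regions: int = 42
    fs: float = 250.0
    n_states: int = 6
    stickiness: float = 0.95
    state_specs: tuple[StateSpec, ...] | None = None
    noise_sd: float = 1.0
    n_subjects: int = 1
    duration_s: float = 60.0
    seed: int = 0

    def resolved_specs(self) -> tuple[StateSpec, ...]:
        if self.state_specs is None:
            return _default_state_specs(self.n_states, self.n_regions)
        return self.state_specs

    def validate(self) -> None:
        if not (0.0 < self.stickiness < 1.0):
            raise InvalidConfigError(
                f"stickiness must lie in (0, 1); got {self.stickiness}"
            )
        if self.n_states < 1:
            raise InvalidConfigError("n_states must be >= 1")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        for k, spec in enumerate(self.resolved_specs()):
            if spec.freq_hz >= self.fs / 2:
                raise InvalidConfigError(
                    f"state {k}: centre frequency {spec.freq_hz} Hz >= Nyquist "
                    f"({self.fs / 2} Hz)"
                )
            for r in spec.regions:
                if not (0 <= r < self.n_regions):
                    raise InvalidConfigError(
                        f"state {k}: region {r} outside [0, {self.n_regions})"
                    )


@dataclass(frozen=True)
class TaskConfig:
    """Blockwise n-back task layout and optional event-locked state modulation.

    ``evoked_states`` maps a state index to ``(latency_s, window_s, boost)``:
    within ``[onset + latency, onset + latency + window]`` after every listed
    stimulus onset the per-sample transition probability into that state is
    multiplied by ``boost`` (then renormalized), so >1 boosts and <1
    suppresses the state.
    """

    n_blocks: int = 12
    stimuli_per_block: int = 20
    blocks_per_condition: int = 4
    stimulus_duration_s: float = 1.0
    inter_trial_s: float = 1.8
    inter_block_s: float = 5.0
    target_counts: tuple[int, int, int] = (25, 23, 28)
    evoked_states: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def trial_spacing_s(self) -> float:
        return self.stimulus_duration_s + self.inter_trial_s

    def validate(self) -> None:
        if self.n_blocks != 3 * self.blocks_per_condition:
            raise InvalidConfigError(
                f"n_blocks ({self.n_blocks}) must equal 3 x blocks_per_condition "
                f"({self.blocks_per_condition})"
            )
        per_load = self.blocks_per_condition * self.stimuli_per_block
        for load, n_targets in enumerate(self.target_counts):
            if n_targets > per_load:
                raise InvalidConfigError(
                    f"load {load}: {n_targets} targets infeasible for "
                    f"{per_load} trials"
                )

    def total_duration_s(self) -> float:
        block_len = self.stimuli_per_block * self.trial_spacing_s
        return self.n_blocks * block_len + (self.n_blocks - 1) * self.inter_block_s


@dataclass
class GroundTruth:
    """Exact generative quantities behind one simulated subject."""

    state_path: np.ndarray  # (n_samples,) int, values in [0, K)
    transition_matrix: np.ndarray  # (K, K) row-stochastic base matrix
    event_table: EventTable | None
    state_specs: tuple[StateSpec, ...]
    fs: float

    def occupancy(self) -> np.ndarray:
        k = self.transition_matrix.shape[0]
        return np.bincount(self.state_path, minlength=k) / self.state_path.size


def sticky_transition_matrix(n_states: int, stickiness: float) -> np.ndarray:
    """Row-stochastic matrix with ``stickiness`` on the diagonal and the
    remaining mass spread uniformly over the off-diagonal entries."""
    if not (0.0 < stickiness < 1.0):
        raise InvalidConfigError(f"stickiness must lie in (0, 1); got {stickiness}")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - stickiness) / (n_states - 1)
    mat = np.full((n_states, n_states), off)
    np.fill_diagonal(mat, stickiness)
    return mat


def _boost_schedule(
    task: TaskConfig, events: EventTable, n_samples: int, fs: float, n_states: int
) -> np.ndarray | None:
    """Per-sample multiplicative factor on each state's transition probability."""
    if not task.evoked_states:
        return None
    factors = np.ones((n_samples, n_states))
    onsets = events.onsets_s
    for state, (latency, window, boost) in task.evoked_states.items():
        if not (0 <= state < n_states):
            raise InvalidConfigError(f"evoked state {state} outside [0, {n_states})")
        for onset in onsets:
            lo = int(round((onset + latency) * fs))
            hi = int(round((onset + latency + window) * fs))
            lo = max(lo, 0)
            hi = min(hi, n_samples)
            if lo < hi:
                factors[lo:hi, state] *= boost
    return factors


def simulate_state_path(
    cfg: SimConfig,
    task: TaskConfig | None = None,
    events: EventTable | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Sample the hidden state path of one subject.

    The chain starts from the uniform distribution and follows the sticky
    transition matrix.  If ``task`` (with ``evoked_states``) is given, the
    transition probabilities are modulated multiplicatively inside each
    event-locked window and renormalized, keeping the path a valid
    (inhomogeneous) Markov chain.  ``events`` defaults to a fresh draw from
    :func:`simulate_task_events` with the same seed.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.n_states
    base = sticky_transition_matrix(k, cfg.stickiness)
    n_samples = int(round(cfg.duration_s * cfg.fs))

    if task is not None:
        task.validate()
        if events is None:
            events = simulate_task_events(task, seed=cfg.seed)
        factors = _boost_schedule(task, events, n_samples, cfg.fs, k)
    else:
        factors = None

    path = np.empty(n_samples, dtype=np.int64)
    if k == 1:
        path[:] = 0
        return GroundTruth(path, base, events, cfg.resolved_specs(), cfg.fs)

    u = rng.random(n_samples)
    probs_init = np.full(k, 1.0 / k)
    if factors is not None:
        p0 = probs_init * factors[0]
        probs_init = p0 / p0.sum()
    path[0] = np.searchsorted(np.cumsum(probs_init), u[0], side="right")
    for t in range(1, n_samples):
        row = base[path[t - 1]]
        if factors is not None:
            row = row * factors[t]
            row = row / row.sum()
        path[t] = np.searchsorted(np.cumsum(row), u[t], side="right")
    np.clip(path, 0, k - 1, out=path)
    return GroundTruth(path, base, events, cfg.resolved_specs(), cfg.fs)


def _visit_runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (state, start, stop) runs of a hard state path."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [path.size]))
    return [(int(path[s]), int(s), int(e)) for s, e in zip(starts, stops)]


def render_recording(
    truth: GroundTruth,
    cfg: SimConfig,
    subject_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> Recording:
    """Render the observed multichannel recording from a hidden state path.

    During each contiguous visit to a state, the state's regions carry a
    sinusoid at its centre frequency with a fresh random initial phase per
    visit (deterministic within the visit, so the spectral ground truth is
    exact); per-region phase lags shift the sinusoid in time.  All regions
    carry independent white noise of ``cfg.noise_sd``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    path = truth.state_path
    n = path.size
    data = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_regions, n))
    specs = truth.state_specs
    for state, start, stop in _visit_runs(path):
        spec = specs[state]
        if not spec.regions:
            continue
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(start, stop) / truth.fs
        amps = spec.amplitudes()
        lags = spec.lags()
        omega = 2.0 * np.pi * spec.freq_hz
        for r, amp, lag in zip(spec.regions, amps, lags):
            data[r, start:stop] += amp * np.sin(omega * (t - lag) + phase0)
    names = [f"region_{i:02d}" for i in range(cfg.n_regions)]
    return Recording(data=data, fs=truth.fs, region_names=names, subject_id=subject_id)


def simulate_task_events(task: TaskConfig, seed: int = 0) -> EventTable:
    """Draw one pseudo-random blockwise n-back session.

    Blocks are assigned to load conditions by a seeded permutation with
    exactly ``blocks_per_condition`` blocks per load; within each load the
    stated number of targets is placed uniformly at random over the feasible
    trial positions (an n-back target needs at least n preceding stimuli in
    its block); all remaining trials are distractors.  Onsets within a block
    are spaced ``stimulus_duration_s + inter_trial_s`` apart.
    """
    task.validate()
    rng = np.random.default_rng(seed)
    loads = np.repeat(np.arange(3), task.blocks_per_condition)
    loads = rng.permutation(loads)

    # choose target positions per load over the pooled feasible slots
    target_slots: dict[int, set[tuple[int, int]]] = {0: set(), 1: set(), 2: set()}
    for load in range(3):
        blocks = np.flatnonzero(loads == load)
        # prefer positions with >= load preceding stimuli in the block (an
        # n-back target needs n predecessors); fall back to all positions
        # when the requested count exceeds the preferred slots
        slots = [
            (int(b), i)
            for b in blocks
            for i in range(load, task.stimuli_per_block)
        ]
        if task.target_counts[load] > len(slots):
            slots = [
                (int(b), i) for b in blocks for i in range(task.stimuli_per_block)
            ]
        chosen = rng.choice(len(slots), size=task.target_counts[load], replace=False)
        target_slots[load] = {slots[int(c)] for c in chosen}

    rows = []
    block_len = task.stimuli_per_block * task.trial_spacing_s
    for b in range(task.n_blocks):
        load = int(loads[b])
        block_start = b * (block_len + task.inter_block_s)
        for i in range(task.stimuli_per_block):
            onset = block_start + i * task.trial_spacing_s
            is_target = (b, i) in target_slots[load]
            cond = f"{load}{'T' if is_target else 'D'}"
            rows.append((onset, cond, b))
    frame = pd.DataFrame(rows, columns=["onset_s", "condition", "block"])
    return EventTable(frame)
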