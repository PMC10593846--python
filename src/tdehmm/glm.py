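"""Two-level GLM on epoched state courses with permutation max-statistics.

First level: per subject, per (state, timepoint), an ordinary least-squares
fit of trialwise baseline-corrected occupancy on a design with a constant
plus the six demeaned condition indicators (0/1/2-back x target/distractor);
contrasts of the parameter estimates (COPEs) test condition effects.  The
six demeaned indicators sum to the zero vector, so the design is solved by
minimum-norm least squares; the constant then estimates the average activity
over all task conditions and all listed contrasts are estimable.

Second level: the across-subject mean COPE at each (state, timepoint) is
tested against zero with a sign-flip permutation null.  Family-wise error
across states and time is controlled by maximum statistics: each permutation
records the maximum over states and time of the signed statistic, and the
observed |statistic| is compared with the 97.5th percentile of that null —
two-sided at p < 0.025 per tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import EpochedCourse

__all__ = [
    "GLMDesign",
    "PermutationResult",
    "build_design",
    "first_level",
    "second_level_permutation",
    "CONTRAST_NAMES",
]

_CONDITIONS = ("0T", "1T", "2T", "0D", "1D", "2D")

#: constant (average across conditions), target-vs-distractor per load,
#: and load differences pooling target and distractor trials
CONTRAST_NAMES = (
    "mean",
    "T-D load0",
    "T-D load1",
    "T-D load2",
    "load1-load0",
    "load2-load0",
    "load2-load1",
)


def _contrast_matrix() -> np.ndarray:
    idx = {c: i + 1 for i, c in enumerate(_CONDITIONS)}  # column 0 = constant
    c = np.zeros((len(CONTRAST_NAMES), 7))
    c[0, 0] = 1.0
    for row, load in zip((1, 2, 3), (0, 1, 2)):
        c[row, idx[f"{load}T"]] = 1.0
        c[row, idx[f"{load}D"]] = -1.0
    pairs = ((4, 1, 0), (5, 2, 0), (6, 2, 1))
    for row, hi, lo in pairs:
        for suffix in "TD":
            c[row, idx[f"{hi}{suffix}"]] = 0.5
            c[row, idx[f"{lo}{suffix}"]] = -0.5
    return c


@dataclass
class GLMDesign:
    """Trials x 7 design matrix (constant + demeaned condition indicators)."""

    matrix: np.ndarray
    contrasts: np.ndarray  # (n_contrasts, 7)
    contrast_names: tuple[str, ...]
    conditions: np.ndarray


def build_design(conditions: Sequence[str]) -> GLMDesign:
    """Build the 7-regressor design from per-trial condition labels.

    Condition indicators are demeaned so the constant regressor captures the
    average activity over all task conditions.
    """
    conditions = np.asarray(conditions)
    n = conditions.size
    mat = np.zeros((n, 7))
    mat[:, 0] = 1.0
    for j, cond in enumerate(_CONDITIONS):
        col = (conditions == cond).astype(float)
        mat[:, j + 1] = col - col.mean()
    return GLMDesign(
        matrix=mat,
        contrasts=_contrast_matrix(),
        contrast_names=CONTRAST_NAMES,
        conditions=conditions,
    )


def first_level(
    epochs: EpochedCourse,
    design: GLMDesign | None = None,
    require_all_conditions: bool = True,
    subject: str = "",
) -> np.ndarray:
    """Per-subject COPEs, shape (n_states, n_times, n_contrasts).

    Fits the design at every (state, timepoint) by minimum-norm least
    squares and applies the contrast vectors to the coefficient estimates.
    """
    if design is None:
        design = build_design(epochs.conditions)
    present = set(np.unique(design.conditions))
    if require_all_conditions:
        missing = [c for c in _CONDITIONS if c not in present]
        if missing:
            raise ValueError(
                f"subject {subject or '<unnamed>'}: no trials for "
                f"condition(s) {missing}"
            )
    n_trials, n_times, n_states = epochs.data.shape
    if design.matrix.shape[0] != n_trials:
        raise ValueError(
            f"design has {design.matrix.shape[0]} rows for {n_trials} trials"
        )
    y = epochs.data.reshape(n_trials, n_times * n_states)
    beta = np.linalg.pinv(design.matrix) @ y  # (7, times*states)
    copes = design.contrasts @ beta  # (n_contrasts, times*states)
    copes = copes.reshape(-1, n_times, n_states)
    return np.transpose(copes, (2, 1, 0))  # (states, times, contrasts)


@dataclass
class PermutationResult:
    """Group-level permutation test output.

    ``group_cope`` is the across-subject mean COPE; ``null_max`` holds, per
    contrast, the permutation distribution of the maximum signed statistic
    over states and time; ``threshold`` its 97.5th percentile; ``mask`` marks
    (state, time, contrast) cells whose |group mean| reaches the threshold.
    """

    group_cope: np.ndarray  # (states, times, contrasts)
    null_max: np.ndarray  # (n_perm, contrasts)
    threshold: np.ndarray  # (contrasts,)
    mask: np.ndarray  # bool, same shape as group_cope
    n_permutations: int
    alpha: float


def second_level_permutation(
    copes: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.025,
    seed: int = 0,
) -> PermutationResult:
    """Sign-flip permutation test of the across-subject mean COPE.

    ``copes`` is (subjects, states, times, contrasts).  Each permutation
    flips the sign of whole subjects and records the maximum over states and
    time of the signed mean, per contrast; the observed |mean| is compared
    with the ``1 - alpha`` percentile of that maximum null (two-sided at
    ``alpha`` per tail, family-wise over states and time).
    """
    copes = np.asarray(copes, dtype=float)
    if copes.ndim != 4:
        raise ValueError("copes must be (subjects, states, times, contrasts)")
    n_subj = copes.shape[0]
    if n_subj < 2:
        raise ValueError("second-level permutation requires >= 2 subjects")
    if n_perm < 20:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} gives an unstable percentile estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    observed = copes.mean(axis=0)  # (states, times, contrasts)
    n_contrasts = copes.shape[3]
    flat = copes.reshape(n_subj, -1, n_contrasts)
    null_max = np.empty((n_perm, n_contrasts))
    for p in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n_subj)
        stat = np.einsum("s,sxc->xc", signs, flat) / n_subj
        null_max[p] = stat.max(axis=0)
    threshold = np.quantile(null_max, 1.0 - alpha, axis=0)
    abs_obs = np.abs(observed)
    mask = (abs_obs >= threshold[None, None, :]) & (abs_obs > 0)
    return PermutationResult(
        group_cope=observed,
        null_max=null_max,
        threshold=threshold,
        mask=mask,
        n_permutations=n_perm,
        alpha=alpha,
    )
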