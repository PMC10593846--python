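"""End-to-end pipeline: simulate -> preprocess -> fit -> metrics -> GLM ->
spectra/modes/thresholding, with provenance stamping and deterministic reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import io as io_mod
from .hmm import FitOptions, fit_vb
from .metrics import epoch_and_baseline, temporal_stats
from .preprocess import EmbeddingSpec, preprocess_group
from .simulate import (
    SimConfig,
    TaskConfig,
    render_recording,
    simulate_state_path,
    simulate_task_events,
)
from .spectra import (
    MultitaperOptions,
    gmm_threshold,
    nnmf_modes,
    project_and_zscore,
    weighted_multitaper,
)
from .types import EventTable, Recording, StateTimeCourse

logger = logging.getLogger("tdehmm")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters of one run.  ``seed`` is mandatory and feeds
    every source of randomness (simulation, restarts, permutations, NNMF)."""

    seed: int | None = None
    # simulation (used when no input recordings are given)
    simulate: bool = True
    n_subjects: int = 6
    n_regions: int = 10
    n_states: int = 3
    fs: float = 250.0
    duration_s: float = 120.0
    stickiness: float = 0.98
    noise_sd: float = 1.0
    with_task: bool = True
    # desk-scale task layout (the full 12-block session lasts ~12 min; the
    # demo keeps the blockwise structure but fits a short recording)
    task_blocks_per_condition: int = 2
    task_stimuli_per_block: int = 4
    task_target_counts: tuple[int, int, int] = (2, 2, 2)
    task_boost: dict = field(default_factory=lambda: {0: (0.2, 0.3, 3.0)})
    # embedding / PCA
    lags: tuple[int, ...] = tuple(range(-7, 8))
    n_components: int | None = None
    orthogonalize: bool = True
    # HMM
    k: int | None = None  # defaults to n_states for simulated runs
    n_restarts: int = 2
    max_iter: int = 30
    # GLM
    n_perm: int = 250
    alpha: float = 0.025
    # spectra
    band: tuple[float, float] = (1.0, 40.0)
    n_modes: int = 4
    # input paths (optional; overrides simulation)
    recording_paths: list[str] = field(default_factory=list)
    event_paths: list[str] = field(default_factory=list)
    out_dir: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("PipelineConfig.seed must be set explicitly")


@dataclass
class PipelineResult:
    recordings: list[Recording]
    event_tables: list[EventTable]
    ground_truths: list[Any]
    params: Any
    courses: list[StateTimeCourse]
    stats: list[Any]
    epochs: list[Any]
    glm: Any
    estimates: list[Any]
    modes: Any
    psd_maps: np.ndarray | None
    networks: dict[tuple[int, int], Any]
    provenance: dict[str, Any]


def _split_course(course: StateTimeCourse, index_maps) -> list[StateTimeCourse]:
    bounds = course.subject_boundaries
    n = course.gamma.shape[0]
    edges = list(bounds) + [n]
    out = []
    for i in range(len(edges) - 1):
        out.append(
            StateTimeCourse(
                gamma=course.gamma[edges[i] : edges[i + 1]],
                sample_indices=index_maps[i],
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and return all artifacts.

    Identical configurations produce identical outputs.  If ``cfg.out_dir``
    is set, completed artifacts are persisted stage by stage (TSV/HDF5) with
    the config hash and seed stamped on each, and a stage failure leaves the
    artifacts of completed stages on disk.
    """
    cfg.validate()
    chash = io_mod.config_hash(cfg.to_dict())
    prov = {"config_hash": chash, "seed": cfg.seed}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        io_mod.save_config(out / "config.yaml", cfg.to_dict())

    stage = "inputs"
    try:
        truths: list[Any] = []
        if cfg.recording_paths:
            recordings, event_tables = io_mod.read_inputs(
                cfg.recording_paths, cfg.event_paths or None
            )
        else:
            stage = "simulate"
            recordings, event_tables = [], []
            task = (
                TaskConfig(
                    n_blocks=3 * cfg.task_blocks_per_condition,
                    blocks_per_condition=cfg.task_blocks_per_condition,
                    stimuli_per_block=cfg.task_stimuli_per_block,
                    target_counts=cfg.task_target_counts,
                    evoked_states={
                        int(k): tuple(v) for k, v in cfg.task_boost.items()
                    },
                )
                if cfg.with_task
                else None
            )
            for s in range(cfg.n_subjects):
                sim = SimConfig(
                    n_regions=cfg.n_regions,
                    fs=cfg.fs,
                    n_states=cfg.n_states,
                    stickiness=cfg.stickiness,
                    noise_sd=cfg.noise_sd,
                    duration_s=cfg.duration_s,
                    seed=cfg.seed + 1000 * s,
                )
                events = None
                if task is not None:
                    events = _fit_events_to_duration(task, sim, cfg.seed + s)
                truth = simulate_state_path(sim, task=task, events=events)
                rec = render_recording(truth, sim, subject_id=f"sub-{s:02d}")
                recordings.append(rec)
                truths.append(truth)
                event_tables.append(truth.event_table)
                if out:
                    io_mod.write_recording(out / f"sub-{s:02d}_rec.h5", rec, prov)
                    if truth.event_table is not None:
                        io_mod.write_events(
                            out / f"sub-{s:02d}_events.tsv", truth.event_table
                        )

        stage = "preprocess"
        spec = EmbeddingSpec(lags=cfg.lags, n_components=cfg.n_components)
        reduced, boundaries, index_maps, pca = preprocess_group(
            recordings, spec, orthogonalize=cfg.orthogonalize
        )

        stage = "fit"
        k = cfg.k if cfg.k is not None else cfg.n_states
        params, course = fit_vb(
            reduced,
            k,
            boundaries=boundaries,
            options=FitOptions(
                n_restarts=cfg.n_restarts, max_iter=cfg.max_iter, seed=cfg.seed
            ),
        )
        courses = _split_course(course, index_maps)
        if out:
            for i, c in enumerate(courses):
                io_mod.write_state_course(out / f"sub-{i:02d}_gamma.h5", c, prov)

        stage = "metrics"
        stats = [temporal_stats(c, recordings[i].fs) for i, c in enumerate(courses)]
        if out:
            for i, st in enumerate(stats):
                io_mod.write_temporal_stats(out / f"sub-{i:02d}_stats.tsv", st)

        epochs, glm_result = [], None
        if event_tables and all(e is not None for e in event_tables):
            stage = "glm"
            copes = []
            for i, c in enumerate(courses):
                ep = epoch_and_baseline(c, event_tables[i], recordings[i].fs)
                epochs.append(ep)
                copes.append(glm_mod.first_level(ep, subject=f"sub-{i:02d}"))
            if len(copes) >= 2:
                glm_result = glm_mod.second_level_permutation(
                    np.asarray(copes),
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=cfg.seed,
                )
                if out:
                    _write_glm_tsv(out / "glm.tsv", glm_result, recordings[0].fs)

        stage = "spectra"
        estimates = [
            weighted_multitaper(recordings[i], courses[i], band=cfg.band)
            for i in range(len(recordings))
        ]
        modes = nnmf_modes(estimates, n_modes=cfg.n_modes, seed=cfg.seed)
        psd_maps, coh = project_and_zscore(estimates, modes)
        networks = {}
        r = recordings[0].n_regions
        iu = np.triu_indices(r, k=1)
        for state in range(k):
            for m in range(cfg.n_modes):
                vals = coh[state, m][iu]
                if np.isnan(vals).any() or vals.size < 4:
                    continue
                networks[(state, m)] = gmm_threshold(
                    vals, pairs=np.column_stack(iu), seed=cfg.seed
                )
        if out:
            _write_networks_tsv(out / "networks.tsv", networks)

        return PipelineResult(
            recordings=recordings,
            event_tables=event_tables,
            ground_truths=truths,
            params=params,
            courses=courses,
            stats=stats,
            epochs=epochs,
            glm=glm_result,
            estimates=estimates,
            modes=modes,
            psd_maps=psd_maps,
            networks=networks,
            provenance=prov,
        )
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise


def _fit_events_to_duration(
    task: TaskConfig, sim: SimConfig, seed: int
) -> EventTable:
    """Draw a task session, checking the recording can hold every trial
    plus a full post-stimulus epoch (truncating would silently lose whole
    conditions and corrupt the GLM design)."""
    needed = task.total_duration_s() + 1.3
    if needed > sim.duration_s:
        raise ValueError(
            f"task layout needs {needed:.1f} s but recordings last "
            f"{sim.duration_s:.1f} s; shrink the task (blocks/stimuli) or "
            "increase duration_s"
        )
    return simulate_task_events(task, seed=seed)


def _write_glm_tsv(path, result, fs: float) -> None:
    rows = []
    n_states, n_times, n_contrasts = result.group_cope.shape
    lo = -0.2
    for s in range(n_states):
        for t in range(n_times):
            for c in range(n_contrasts):
                rows.append(
                    (
                        s,
                        round((lo + t / fs) * 1000.0, 3),
                        glm_mod.CONTRAST_NAMES[c],
                        result.group_cope[s, t, c],
                        bool(result.mask[s, t, c]),
                    )
                )
    pd.DataFrame(
        rows, columns=["state", "time_ms", "contrast", "cope", "significant"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_networks_tsv(path, networks) -> None:
    rows = []
    for (state, mode), net in sorted(networks.items()):
        for i, j, v in net.kept:
            rows.append((state, mode, i, j, v))
    pd.DataFrame(
        rows, columns=["state", "mode", "region_i", "region_j", "value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
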