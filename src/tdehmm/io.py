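"""On-disk formats: HDF5 for arrays, TSV for tables, YAML for configs.

Every writer stamps provenance attributes (config hash, package version,
seed) so pipeline outputs are traceable to the exact run that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import EpochedCourse, TemporalStats
from .types import EventTable, Recording, StateTimeCourse

__all__ = [
    "config_hash",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_state_course",
    "read_state_course",
    "write_temporal_stats",
    "read_inputs",
    "load_config",
    "save_config",
]


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(group: h5py.File | h5py.Group, provenance: dict[str, Any] | None) -> None:
    group.attrs["tdehmm_version"] = __version__
    for key, val in (provenance or {}).items():
        group.attrs[key] = val


def write_recording(
    path: str | Path, rec: Recording, provenance: dict[str, Any] | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["region_names"] = [str(n) for n in rec.region_names]
        f.attrs["subject_id"] = rec.subject_id
        _stamp(f, provenance)


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: missing dataset 'data'")
        data = f["data"][...]
        if "fs" not in f.attrs:
            raise ValueError(f"{path}: missing attribute 'fs'")
        fs = float(f.attrs["fs"])
        names = [str(n) for n in f.attrs.get("region_names", [])]
        if not names:
            names = [f"region_{i:02d}" for i in range(data.shape[0])]
        subject = str(f.attrs.get("subject_id", path.stem))
    return Recording(data=data, fs=fs, region_names=names, subject_id=subject)


def write_events(path: str | Path, events: EventTable) -> None:
    events.frame.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventTable:
    frame = pd.read_csv(path, sep="\t")
    try:
        return EventTable(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_state_course(
    path: str | Path,
    course: StateTimeCourse,
    provenance: dict[str, Any] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gamma", data=course.gamma)
        if course.xi is not None:
            f.create_dataset("xi", data=course.xi)
        if course.subject_boundaries is not None:
            f.create_dataset("subject_boundaries", data=course.subject_boundaries)
        if course.sample_indices is not None:
            f.create_dataset("sample_indices", data=course.sample_indices)
        if course.free_energy_trace is not None:
            f.create_dataset("free_energy_trace", data=course.free_energy_trace)
        if course.log_likelihood is not None:
            f.attrs["log_likelihood"] = course.log_likelihood
        _stamp(f, provenance)


def read_state_course(path: str | Path) -> StateTimeCourse:
    with h5py.File(path, "r") as f:
        return StateTimeCourse(
            gamma=f["gamma"][...],
            xi=f["xi"][...] if "xi" in f else None,
            subject_boundaries=(
                f["subject_boundaries"][...] if "subject_boundaries" in f else None
            ),
            sample_indices=(
                f["sample_indices"][...] if "sample_indices" in f else None
            ),
            log_likelihood=(
                float(f.attrs["log_likelihood"])
                if "log_likelihood" in f.attrs
                else None
            ),
            free_energy_trace=(
                f["free_energy_trace"][...] if "free_energy_trace" in f else None
            ),
        )


def write_temporal_stats(path: str | Path, stats: TemporalStats) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_inputs(
    recording_paths: list[str | Path],
    event_paths: list[str | Path] | None = None,
) -> tuple[list[Recording], list[EventTable]]:
    """Load and cross-validate a group of recordings (and event tables).

    All subjects must share the region count and sampling rate; onsets must
    fall inside their recording.
    """
    recs = [read_recording(p) for p in recording_paths]
    first = recs[0]
    for p, rec in zip(recording_paths, recs):
        if rec.n_regions != first.n_regions:
            raise ValueError(
                f"{p}: {rec.n_regions} regions but {recording_paths[0]} has "
                f"{first.n_regions}"
            )
        if rec.fs != first.fs:
            raise ValueError(f"{p}: fs {rec.fs} != {first.fs}")
    events: list[EventTable] = []
    if event_paths:
        if len(event_paths) != len(recs):
            raise ValueError("one event table per recording required")
        for p, rec in zip(event_paths, recs):
            table = read_events(p)
            if (table.onsets_s >= rec.duration_s).any():
                raise ValueError(f"{p}: onset beyond recording end")
            events.append(table)
    return recs, events


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path: str | Path, cfg: dict[str, Any]) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
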