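"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import tdehmm as t

BENCHMARK_FREQS = (6.0, 10.0, 20.0)
BENCHMARK_STICKINESS = 0.98


def benchmark_specs() -> tuple[t.StateSpec, ...]:
    return (
        t.StateSpec(regions=(0, 1, 2), freq_hz=6.0, amplitude=2.0),
        t.StateSpec(regions=(3, 4, 5), freq_hz=10.0, amplitude=2.0),
        t.StateSpec(regions=(6, 7, 8), freq_hz=20.0, amplitude=2.0),
    )


def run_benchmark(duration_s: float = 400.0, seed: int = 7, fit_seed: int = 11,
                  n_restarts: int = 2, max_iter: int = 50) -> dict:
    """Simulate the 3-state oscillatory benchmark (10 regions, stickiness
    0.98, networks at 6/10/20 Hz) and fit the full TDE-HMM pipeline on it."""
    cfg = t.SimConfig(
        n_regions=10, fs=250.0, n_states=3, stickiness=BENCHMARK_STICKINESS,
        state_specs=benchmark_specs(), noise_sd=1.0, duration_s=duration_s,
        seed=seed,
    )
    truth = t.simulate_state_path(cfg)
    rec = t.render_recording(truth, cfg)
    reduced, bounds, maps, pca = t.preprocess_group(
        [rec], t.EmbeddingSpec(), orthogonalize=False
    )
    params, course = t.fit_vb(
        reduced, 3, boundaries=bounds,
        options=t.FitOptions(n_restarts=n_restarts, max_iter=max_iter,
                             seed=fit_seed),
    )
    hard = course.hard_path()
    true_path = truth.state_path[maps[0]]
    accs = {
        p: float(np.mean(np.asarray(p)[hard] == true_path))
        for p in itertools.permutations(range(3))
    }
    perm, accuracy = max(accs.items(), key=lambda kv: kv[1])
    return {
        "cfg": cfg,
        "truth": truth,
        "recording": rec,
        "reduced": reduced,
        "index_map": maps[0],
        "params": params,
        "course": course,
        "perm": np.asarray(perm),  # perm[fitted] = true state
        "accuracy": accuracy,
    }


@pytest.fixture(scope="session")
def benchmark_fit() -> dict:
    return run_benchmark()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
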