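"""Leakage correction, time-delay embedding and PCA reduction.

This stage turns a parcellated recording into the matrix a covariance-based
hidden Markov model is fit on.  Symmetric orthogonalization removes zero-lag
(volume-conduction / leakage) correlations without preferring any region;
time-delay embedding stacks lagged copies of every region so that state
covariances capture frequency-resolved power and phase-coupling; PCA reduces
the stacked matrix to a tractable number of components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Recording

__all__ = [
    "EmbeddingSpec",
    "PCAModel",
    "orthogonalize_symmetric",
    "build_embedded",
    "pca_fit_apply",
    "preprocess_group",
    "RankError",
]


class RankError(ValueError):
    """Input matrix does not have the rank an operation requires."""


@dataclass(frozen=True)
class EmbeddingSpec:
    """Time-delay embedding and reduction parameters.

    ``lags`` default to the symmetric window -7..+7 (15 values, 60 ms at
    250 Hz); ``n_components`` defaults to twice the region count when left
    ``None`` (the 2 x ROIs convention).
    """

    lags: tuple[int, ...] = tuple(range(-7, 8))
    n_components: int | None = None
    standardize: bool = True
    standardize_scores: bool = False

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def max_abs_lag(self) -> int:
        return max(abs(l) for l in self.lags)

    def resolved_components(self, n_regions: int) -> int:
        if self.n_components is not None:
            return self.n_components
        return 2 * n_regions


@dataclass
class PCAModel:
    """Fitted PCA: mean, orthonormal loadings and explained-variance fractions."""

    mean: np.ndarray  # (n_features,)
    loadings: np.ndarray  # (n_features, P), orthonormal columns
    explained_variance_ratio: np.ndarray  # (P,), non-increasing

    def transform(self, embedded: np.ndarray) -> np.ndarray:
        """Project a features x samples matrix onto the components (P x samples)."""
        return self.loadings.T @ (embedded - self.mean[:, None])

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return self.loadings @ reduced + self.mean[:, None]


def orthogonalize_symmetric(rec: Recording) -> Recording:
    """Multivariate symmetric leakage correction.

    Returns the closest matrix (Frobenius norm) whose rows are mutually
    orthogonal — the orthonormal polar factor of the demeaned data — rescaled
    so each row keeps its original norm.  No region is treated as a
    reference: permuting regions commutes with the operation.
    """
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < n:
        raise RankError(
            f"symmetric orthogonalization needs full row rank: rank {rank} < "
            f"{n} regions (region time series are linearly dependent)"
        )
    # closest matrix with orthonormal rows is U V^T (polar factor)
    w = u @ vt
    norms = np.linalg.norm(x, axis=1)
    out = w * norms[:, None]
    return Recording(
        data=out, fs=rec.fs, region_names=list(rec.region_names),
        subject_id=rec.subject_id,
    )


def build_embedded(
    rec: Recording, spec: EmbeddingSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged copies of every region.

    Returns ``(embedded, sample_indices)``: ``embedded`` has
    ``n_regions * n_lags`` rows ordered region-major (all lags of region 0,
    then region 1, ...); row ``(r, l)`` at column ``t`` holds region ``r`` at
    original sample ``sample_indices[t] + l``.  The ``max |lag|`` samples at
    each edge, where some lag would fall outside the recording, are dropped;
    ``sample_indices`` records the surviving original sample indices.
    """
    m = spec.max_abs_lag
    n = rec.n_samples
    if n <= 2 * m:
        raise ValueError(
            f"recording too short for embedding: {n} samples <= 2 x max lag {m}"
        )
    valid = np.arange(m, n - m)
    rows = []
    for r in range(rec.n_regions):
        for lag in spec.lags:
            rows.append(rec.data[r, valid + lag])
    return np.asarray(rows), valid


def pca_fit_apply(
    embedded: np.ndarray, spec: EmbeddingSpec, n_regions: int | None = None
) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA on a features x samples embedded matrix and project onto it.

    The reduced matrix is ``loadings.T @ (embedded - mean)`` (P x samples).
    Raises if more components are requested than the matrix's rank supports.
    """
    if n_regions is None:
        if embedded.shape[0] % max(len(spec.lags), 1) == 0:
            n_regions = embedded.shape[0] // len(spec.lags)
        else:
            n_regions = embedded.shape[0]
    p = spec.resolved_components(n_regions)
    n_feat, n_samp = embedded.shape
    if p > min(n_feat, n_samp):
        raise RankError(
            f"cannot extract {p} components from a {n_feat} x {n_samp} matrix"
        )
    mean = embedded.mean(axis=1)
    centered = embedded - mean[:, None]
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    rank = int((s > s[0] * max(embedded.shape) * np.finfo(float).eps).sum()) if s[0] > 0 else 0
    if p > rank:
        raise RankError(f"requested {p} components but matrix rank is {rank}")
    loadings = u[:, :p]
    ratio = var[:p] / total if total > 0 else np.zeros(p)
    model = PCAModel(mean=mean, loadings=loadings, explained_variance_ratio=ratio)
    reduced = loadings.T @ centered
    if spec.standardize_scores:
        sd = reduced.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        reduced = reduced / sd
    return model, reduced


def preprocess_group(
    recordings: list[Recording],
    spec: EmbeddingSpec | None = None,
    orthogonalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], PCAModel]:
    """Full preprocessing of a group of subjects.

    Per subject: (optional) symmetric orthogonalization, per-region z-scoring
    (when ``spec.standardize``), time-delay embedding.  The embedded matrices
    are concatenated across subjects and a single group PCA is fit, matching
    the group-level concatenated inference downstream.

    Returns ``(reduced, boundaries, index_maps, pca)`` where ``reduced`` is
    P x total_samples, ``boundaries`` holds each subject's start offset in the
    concatenated axis, and ``index_maps[i]`` maps subject ``i``'s columns back
    to original sample indices (for event alignment).
    """
    if spec is None:
        spec = EmbeddingSpec()
    embedded_parts: list[np.ndarray] = []
    index_maps: list[np.ndarray] = []
    for rec in recordings:
        if orthogonalize:
            rec = orthogonalize_symmetric(rec)
        data = rec.data
        if spec.standardize:
            mu = data.mean(axis=1, keepdims=True)
            sd = data.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            data = (data - mu) / sd
            rec = Recording(data, rec.fs, list(rec.region_names), rec.subject_id)
        emb, idx = build_embedded(rec, spec)
        embedded_parts.append(emb)
        index_maps.append(idx)
    lengths = [e.shape[1] for e in embedded_parts]
    boundaries = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    embedded = np.concatenate(embedded_parts, axis=1)
    pca, reduced = pca_fit_apply(embedded, spec, n_regions=recordings[0].n_regions)
    return reduced, boundaries, index_maps, pca
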