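"""State-specific spectra: gamma-weighted multitaper PSD and coherence,
NNMF frequency modes, z-scored power maps and GMM network thresholding.

The recording is cut into overlapping windows; each window's DPSS multitaper
cross-spectrum contributes to every state's estimate with weight equal to
the window's mean posterior probability for that state.  PSD is the
cross-spectrum diagonal; coherence is the normalized cross-spectrum
magnitude.  Pooled over subjects, states, regions (PSD columns) and region
pairs (coherence columns), the spectra are factorized by non-negative matrix
factorization into a small number of frequency modes (data-driven analogues
of the canonical theta/alpha/beta bands); projecting spectra onto a mode and
thresholding the resulting connection strengths with a two-component
Gaussian mixture yields the mode-specific phase-coupling network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as sp_windows
from sklearn.decomposition import NMF
from sklearn.mixture import GaussianMixture

from .types import Recording, StateTimeCourse

__all__ = [
    "MultitaperOptions",
    "SpectralEstimate",
    "SpectralModes",
    "ThresholdedNetwork",
    "weighted_multitaper",
    "nnmf_modes",
    "project_and_zscore",
    "gmm_threshold",
]


@dataclass(frozen=True)
class MultitaperOptions:
    """Multitaper settings: 2 s windows with 50% overlap, time-half-bandwidth
    4 and 7 DPSS tapers — standard resolution for a 1-40 Hz analysis at
    250 Hz sampling."""

    window_s: float = 2.0
    overlap: float = 0.5
    bandwidth: float = 4.0  # time-half-bandwidth product NW
    n_tapers: int = 7


@dataclass
class SpectralEstimate:
    """Per-state PSD and coherence of one subject on a common frequency grid.

    ``psd`` is (K, F, R) and non-negative; ``coherence`` is (K, F, R, R),
    symmetric in the region axes with unit diagonal.  States whose total
    posterior weight is ~0 carry NaN and are listed in ``missing_states``.
    """

    freqs: np.ndarray
    psd: np.ndarray
    coherence: np.ndarray
    state_weights: np.ndarray
    options: MultitaperOptions
    missing_states: list[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.psd.shape[0]

    @property
    def n_regions(self) -> int:
        return self.psd.shape[2]


def weighted_multitaper(
    rec: Recording,
    course: StateTimeCourse,
    band: tuple[float, float] = (1.0, 40.0),
    options: MultitaperOptions | None = None,
) -> SpectralEstimate:
    """Gamma-weighted multitaper cross-spectra per state.

    The state-k cross-spectrum is the weighted average of windowed multitaper
    cross-spectra, each window weighted by its mean gamma_k; with a single
    always-active state this reduces exactly to the unweighted multitaper
    estimate.  Gamma is aligned to the recording through
    ``course.sample_indices`` (the embedding's surviving-sample map).
    """
    opts = options or MultitaperOptions()
    data = rec.data
    n_regions, n_samples = data.shape
    gamma = course.gamma
    if course.sample_indices is not None:
        offset = int(np.asarray(course.sample_indices)[0])
    else:
        offset = 0
    k_states = gamma.shape[1]

    win_len = int(round(opts.window_s * rec.fs))
    step = max(1, int(round(win_len * (1.0 - opts.overlap))))
    if win_len > gamma.shape[0]:
        raise ValueError("recording shorter than one spectral window")
    tapers = sp_windows.dpss(win_len, opts.bandwidth, Kmax=opts.n_tapers)
    freqs = np.fft.rfftfreq(win_len, d=1.0 / rec.fs)
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    freqs = freqs[fsel]
    n_freq = freqs.size

    sxy = np.zeros((k_states, n_freq, n_regions, n_regions), dtype=complex)
    weights = np.zeros(k_states)
    # windows are laid out on the gamma (valid-sample) axis, then mapped to
    # the raw recording via the index-map offset
    for start in range(0, gamma.shape[0] - win_len + 1, step):
        seg = data[:, offset + start : offset + start + win_len]
        w = gamma[start : start + win_len].mean(axis=0)
        tapered = tapers[:, None, :] * seg[None, :, :]  # (tapers, regions, win)
        spec = np.fft.rfft(tapered, axis=2)[:, :, fsel]
        cross = np.einsum("mif,mjf->fij", spec, np.conj(spec)) / opts.n_tapers
        sxy += w[:, None, None, None] * cross[None]
        weights += w

    missing = []
    psd = np.full((k_states, n_freq, n_regions), np.nan)
    coh = np.full((k_states, n_freq, n_regions, n_regions), np.nan)
    for k in range(k_states):
        if weights[k] <= 1e-12:
            missing.append(k)
            warnings.warn(
                f"state {k} has ~zero total weight; spectra reported missing",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        s = sxy[k] / weights[k]
        p = np.real(np.einsum("fii->fi", s))
        p = np.clip(p, 0.0, None)
        psd[k] = p
        denom = np.sqrt(p[:, :, None] * p[:, None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(s) / denom
        c = np.clip(np.nan_to_num(c), 0.0, 1.0)
        ii = np.arange(n_regions)
        c[:, ii, ii] = 1.0
        coh[k] = 0.5 * (c + np.transpose(c, (0, 2, 1)))
    return SpectralEstimate(
        freqs=freqs,
        psd=psd,
        coherence=coh,
        state_weights=weights / max(weights.sum(), 1e-300),
        options=opts,
        missing_states=missing,
    )


@dataclass
class SpectralModes:
    """NNMF factorization of pooled spectra into frequency modes.

    ``profiles`` is (F, M), non-negative, modes ordered by peak frequency
    ascending; ``loadings`` is (M, n_features) over all pooled (subject,
    state, region) PSD columns followed by (subject, state, pair) coherence
    columns.  ``residual`` is the final Frobenius reconstruction error.
    """

    freqs: np.ndarray
    profiles: np.ndarray
    loadings: np.ndarray
    residual: float
    n_psd_features: int

    @property
    def n_modes(self) -> int:
        return self.profiles.shape[1]


def _pool_features(
    estimates: list[SpectralEstimate], include_coherence: bool
) -> np.ndarray:
    cols = []
    freqs = estimates[0].freqs
    for est in estimates:
        if not np.allclose(est.freqs, freqs):
            raise ValueError("spectral estimates must share the frequency grid")
        r = est.n_regions
        iu = np.triu_indices(r, k=1)
        for k in range(est.n_states):
            if k in est.missing_states:
                continue
            cols.append(est.psd[k])  # (F, R)
    n_psd = sum(c.shape[1] for c in cols)
    if include_coherence:
        for est in estimates:
            r = est.n_regions
            iu = np.triu_indices(r, k=1)
            for k in range(est.n_states):
                if k in est.missing_states:
                    continue
                cols.append(est.coherence[k][:, iu[0], iu[1]])  # (F, pairs)
    return np.concatenate(cols, axis=1), n_psd


def nnmf_modes(
    estimates: list[SpectralEstimate] | np.ndarray,
    n_modes: int = 4,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    include_coherence: bool = True,
    freqs: np.ndarray | None = None,
) -> SpectralModes:
    """Factorize pooled spectra into non-negative frequency modes.

    Accepts either a list of :class:`SpectralEstimate` (pooled jointly over
    PSD and, unless ``include_coherence=False``, coherence features) or a
    raw non-negative (F x features) matrix.  Multiplicative-update NNMF, best
    of ``n_restarts`` by residual; modes are reordered by ascending peak
    frequency.
    """
    if isinstance(estimates, np.ndarray):
        matrix = estimates
        n_psd = matrix.shape[1]
        if freqs is None:
            freqs = np.arange(matrix.shape[0], dtype=float)
    else:
        matrix, n_psd = _pool_features(estimates, include_coherence)
        freqs = estimates[0].freqs
    if (matrix < 0).any():
        raise ValueError("NNMF input must be non-negative (PSD/coherence)")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for r in range(max(1, n_restarts)):
        model = NMF(
            n_components=n_modes,
            solver="mu",
            init="random",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + r,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = model.fit_transform(matrix)  # (F, M)
        h = model.components_  # (M, features)
        resid = float(np.linalg.norm(matrix - w @ h))
        if best is None or resid < best[0]:
            best = (resid, w, h)
    resid, w, h = best
    order = np.argsort([freqs[np.argmax(w[:, m])] for m in range(n_modes)],
                       kind="stable")
    return SpectralModes(
        freqs=freqs,
        profiles=w[:, order],
        loadings=h[order],
        residual=resid,
        n_psd_features=n_psd,
    )


def project_and_zscore(
    estimates: list[SpectralEstimate],
    modes: SpectralModes,
) -> tuple[np.ndarray, np.ndarray]:
    """Project spectra onto each mode and average across subjects.

    Returns ``(psd_maps, coherence)``: ``psd_maps`` is (K, M, R), the group
    PSD map per state and mode z-scored across regions; ``coherence`` is
    (K, M, R, R), the group mode-projected coherence.  The projection is the
    inner product of the spectrum with the mode profile over frequency.
    """
    freqs = estimates[0].freqs
    if not np.allclose(freqs, modes.freqs):
        raise ValueError("mode and estimate frequency grids differ")
    k_states = estimates[0].n_states
    r = estimates[0].n_regions
    m = modes.n_modes
    psd_proj = np.zeros((k_states, m, r))
    coh_proj = np.zeros((k_states, m, r, r))
    counts = np.zeros(k_states)
    for est in estimates:
        for k in range(k_states):
            if k in est.missing_states:
                continue
            psd_proj[k] += np.einsum("fr,fm->mr", est.psd[k], modes.profiles)
            coh_proj[k] += np.einsum("fij,fm->mij", est.coherence[k],
                                     modes.profiles)
            counts[k] += 1
    counts[counts == 0] = 1
    psd_proj /= counts[:, None, None]
    coh_proj /= counts[:, None, None, None]
    mu = psd_proj.mean(axis=2, keepdims=True)
    sd = psd_proj.std(axis=2, keepdims=True)
    sd[sd == 0] = 1.0
    psd_maps = (psd_proj - mu) / sd
    return psd_maps, coh_proj


@dataclass
class ThresholdedNetwork:
    """Connections surviving GMM thresholding for one (state, mode).

    ``kept`` lists (i, j, value) for region pairs whose posterior under the
    higher-mean mixture component exceeds 0.5; ``threshold`` is the smallest
    kept value.  ``fallback`` flags a degenerate mixture where a percentile
    cut replaced the GMM.
    """

    kept: list[tuple[int, int, float]]
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    threshold: float
    fallback: bool = False


def gmm_threshold(
    values: np.ndarray,
    pairs: np.ndarray | None = None,
    seed: int = 0,
    fallback_percentile: float = 95.0,
) -> ThresholdedNetwork:
    """Split connection strengths into background and strong clusters.

    Fits a two-component univariate Gaussian mixture to the pooled values
    and keeps those whose posterior under the higher-mean component exceeds
    0.5.  A degenerate fit (vanishing component variance or weight) falls
    back to a percentile threshold with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 connection values for a 2-GMM")
    if pairs is None:
        r = _implied_size(n)
        if r is not None:
            pairs = np.column_stack(np.triu_indices(r, k=1))
        else:  # not a full upper triangle: label connections by index
            pairs = np.column_stack((np.zeros(n, dtype=int), np.arange(n)))
    spread = values.std()
    degenerate = spread < 1e-12
    fallback = False
    if degenerate:
        means = np.array([values.mean(), values.mean()])
        variances = np.zeros(2)
        weights = np.array([0.5, 0.5])
        posterior_hi = np.zeros(n)
    else:
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        gm.fit(values[:, None])
        means = gm.means_.ravel()
        variances = gm.covariances_.ravel()
        weights = gm.weights_.ravel()
        if variances.min() < 1e-12 * max(spread**2, 1e-30) or weights.min() < 1e-6:
            degenerate = True
            posterior_hi = np.zeros(n)
        else:
            hi = int(np.argmax(means))
            posterior_hi = gm.predict_proba(values[:, None])[:, hi]
    if degenerate:
        fallback = True
        warnings.warn(
            "degenerate Gaussian mixture; falling back to percentile threshold",
            RuntimeWarning,
            stacklevel=2,
        )
        cut = np.percentile(values, fallback_percentile)
        keep_mask = values > cut if spread > 0 else np.zeros(n, dtype=bool)
    else:
        keep_mask = posterior_hi > 0.5
    kept_vals = values[keep_mask]
    threshold = float(kept_vals.min()) if kept_vals.size else float("inf")
    kept = [
        (int(pairs[i, 0]), int(pairs[i, 1]), float(values[i]))
        for i in np.flatnonzero(keep_mask)
    ]
    return ThresholdedNetwork(
        kept=kept,
        means=means,
        variances=variances,
        weights=weights,
        threshold=threshold,
        fallback=fallback,
    )


def _implied_size(n_pairs: int) -> int | None:
    r = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    return r if r * (r - 1) // 2 == n_pairs else None
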