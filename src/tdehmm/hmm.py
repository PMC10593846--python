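"""Variational Bayes Gaussian hidden Markov model on reduced embedded data.

States are multivariate Gaussians whose covariance matrices carry all state
identity (means are fixed at zero by default, appropriate for zero-mean
embedded data): on time-delay-embedded inputs a state covariance encodes
frequency-resolved power and cross-region phase-coupling.  Inference is
variational EM with conjugate priors — Dirichlet on the transition rows and
the initial distribution, inverse-Wishart on the state covariances — so the
free energy is computable in closed form and decreases monotonically across
full-batch iterations.  Posterior state probabilities come from the scaled
forward–backward recursions; hard paths from Viterbi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, multigammaln

from .types import StateTimeCourse

__all__ = [
    "HMMParams",
    "forward_backward",
    "viterbi",
    "fit_vb",
    "align_states",
    "FitOptions",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """Point parameters (posterior means after a fit) plus prior records."""

    pi: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K) row-stochastic
    means: np.ndarray  # (K, P)
    covariances: np.ndarray  # (K, P, P) SPD
    dirichlet_alpha: float = 1.0
    wishart_dof: float | None = None
    free_energy: float | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


def _gaussian_log_density(obs: np.ndarray, means: np.ndarray,
                          covariances: np.ndarray) -> np.ndarray:
    """log N(x_t | mu_k, Sigma_k) for all t, k.  obs is (T, P)."""
    t_n, p = obs.shape
    k_n = means.shape[0]
    out = np.empty((t_n, k_n))
    for k in range(k_n):
        cov = covariances[k]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(
                f"state {k}: covariance is not positive-definite"
            ) from exc
        diff = obs - means[k]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, k] = -0.5 * (p * _LOG2PI + logdet + maha)
    return out


def _segments(n_samples: int, boundaries: np.ndarray | None):
    if boundaries is None:
        return [(0, n_samples)]
    b = list(np.asarray(boundaries, dtype=int)) + [n_samples]
    return [(b[i], b[i + 1]) for i in range(len(b) - 1)]


def _forward_backward_core(
    log_b: np.ndarray,
    log_pi: np.ndarray,
    log_a: np.ndarray,
    boundaries: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.  ``log_a`` rows need not normalize (VB uses
    sub-normalized exp(E[log A])).  Chains restart at each subject boundary.

    Returns (gamma, xi_sum, log_likelihood).
    """
    t_n, k_n = log_b.shape
    a = np.exp(log_a)
    pi = np.exp(log_pi)
    gamma = np.empty((t_n, k_n))
    xi = np.zeros((k_n, k_n))
    loglik = 0.0
    for start, stop in _segments(t_n, boundaries):
        seg = slice(start, stop)
        lb = log_b[seg]
        shift = lb.max(axis=1)
        b = np.exp(lb - shift[:, None])
        n = stop - start
        alpha = np.empty((n, k_n))
        scale = np.empty(n)
        a0 = pi * b[0]
        scale[0] = a0.sum()
        alpha[0] = a0 / scale[0]
        for t in range(1, n):
            at = (alpha[t - 1] @ a) * b[t]
            scale[t] = at.sum()
            alpha[t] = at / scale[t]
        beta = np.empty((n, k_n))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (a @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        gamma[seg] = g
        for t in range(n - 1):
            m = alpha[t][:, None] * a * (b[t + 1] * beta[t + 1])[None, :]
            xi += m / m.sum()
        loglik += float(np.log(scale).sum() + shift.sum())
    return gamma, xi, loglik


def forward_backward(
    params: HMMParams,
    observations: np.ndarray,
    boundaries: np.ndarray | None = None,
) -> StateTimeCourse:
    """Exact smoothing posteriors under fixed point parameters.

    ``observations`` is samples x P.  Scaling constants accumulate to the
    log-likelihood; chains restart from ``params.pi`` at each boundary.
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    if obs.shape[1] != params.n_dims:
        raise ValueError(
            f"observations have {obs.shape[1]} dims, model has {params.n_dims}"
        )
    log_b = _gaussian_log_density(obs, params.means, params.covariances)
    with np.errstate(divide="ignore"):
        gamma, xi, loglik = _forward_backward_core(
            log_b, np.log(params.pi), np.log(params.transition), boundaries
        )
    return StateTimeCourse(
        gamma=gamma, xi=xi, subject_boundaries=boundaries, log_likelihood=loglik
    )


def viterbi(
    params: HMMParams,
    observations: np.ndarray,
    boundaries: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable joint state path; ties break toward the lower state index."""
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    log_b = _gaussian_log_density(obs, params.means, params.covariances)
    with np.errstate(divide="ignore"):
        log_a = np.log(params.transition)
        log_pi = np.log(params.pi)
    t_n, k_n = log_b.shape
    path = np.empty(t_n, dtype=np.int64)
    for start, stop in _segments(t_n, boundaries):
        n = stop - start
        lb = log_b[start:stop]
        delta = log_pi + lb[0]
        back = np.empty((n, k_n), dtype=np.int64)
        for t in range(1, n):
            cand = delta[:, None] + log_a
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(k_n)] + lb[t]
        last = int(np.argmax(delta))
        path[stop - 1] = last
        for t in range(n - 1, 0, -1):
            last = int(back[t, last])
            path[start + t - 1] = last
    return path


# ---------------------------------------------------------------------------
# Variational fitting


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_vb`."""

    max_iter: int = 50
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    learn_means: bool = False
    dirichlet_alpha: float = 1.0
    wishart_dof: float | None = None  # default P + 2
    wishart_scale: float | None = None  # default weak: eps * mean variance * I
    reg: float = 1e-6
    init: str = "blocks"  # "blocks" | "dirichlet"
    init_block_len: int = 100
    minibatch: int | None = None  # subjects per stochastic iteration
    minibatch_forget: float = 0.6
    minibatch_delay: float = 2.0


def _dirichlet_kl(post: np.ndarray, prior: np.ndarray) -> float:
    post = np.atleast_2d(post)
    prior = np.atleast_2d(prior)
    kl = 0.0
    for a, b in zip(post, prior):
        a0, b0 = a.sum(), b.sum()
        kl += (
            gammaln(a0) - gammaln(b0)
            - np.sum(gammaln(a)) + np.sum(gammaln(b))
            + np.sum((a - b) * (digamma(a) - digamma(a0)))
        )
    return float(kl)


def _inverse_wishart_kl(nu1: float, s1: np.ndarray, nu0: float,
                        s0: np.ndarray) -> float:
    """KL between inverse-Wishart posteriors/priors on a covariance, computed
    as the KL between the induced Wisharts on the precision."""
    p = s1.shape[0]
    # W(n, V) on precision with n = nu, V = S^{-1}
    n1, n0 = nu1, nu0
    v1 = np.linalg.inv(s1)
    v0 = np.linalg.inv(s0)
    v0_inv_v1 = np.linalg.solve(v0, v1)
    _, logdet_ratio = np.linalg.slogdet(v0_inv_v1)
    # E_q[log det Lambda] with Lambda ~ W(n1, V1)
    e_logdet = (
        np.sum(digamma(0.5 * (n1 - np.arange(p))))
        + p * np.log(2.0)
        + np.linalg.slogdet(v1)[1]
    )
    log_b1 = -0.5 * n1 * np.linalg.slogdet(v1)[1] - 0.5 * n1 * p * np.log(2.0) \
        - multigammaln(0.5 * n1, p)
    log_b0 = -0.5 * n0 * np.linalg.slogdet(v0)[1] - 0.5 * n0 * p * np.log(2.0) \
        - multigammaln(0.5 * n0, p)
    e_tr = n1 * np.trace(v0_inv_v1)  # E[tr(V0^{-1} Lambda)]
    kl = (
        log_b1 - log_b0
        + 0.5 * (n1 - n0) * e_logdet
        - 0.5 * n1 * p
        + 0.5 * e_tr
    )
    return float(kl)


class _VBState:
    """Posterior hyperparameters of one VB run."""

    def __init__(self, k: int, p: int, opts: FitOptions, data_var: float):
        self.k, self.p = k, p
        self.alpha_pi0 = np.full(k, opts.dirichlet_alpha)
        self.alpha_a0 = np.full((k, k), opts.dirichlet_alpha)
        self.nu0 = opts.wishart_dof if opts.wishart_dof is not None else p + 2.0
        if opts.wishart_scale is not None:
            self.s0 = np.eye(p) * opts.wishart_scale
        else:
            # weak prior: small fraction of the average data variance
            self.s0 = np.eye(p) * (1e-3 * data_var * self.nu0)
        self.alpha_pi = self.alpha_pi0.copy()
        self.alpha_a = self.alpha_a0.copy()
        self.nu = np.full(k, self.nu0)
        self.s = np.tile(self.s0, (k, 1, 1))

    # expected log parameters used in the E-step
    def expected_log_pi(self) -> np.ndarray:
        return digamma(self.alpha_pi) - digamma(self.alpha_pi.sum())

    def expected_log_a(self) -> np.ndarray:
        return digamma(self.alpha_a) - digamma(self.alpha_a.sum(axis=1))[:, None]

    def expected_log_b(self, obs: np.ndarray, means: np.ndarray) -> np.ndarray:
        t_n = obs.shape[0]
        out = np.empty((t_n, self.k))
        for k in range(self.k):
            prec = self.nu[k] * np.linalg.inv(self.s[k])  # E[Sigma^{-1}]
            e_logdet_sigma = (
                np.linalg.slogdet(self.s[k])[1]
                - np.sum(digamma(0.5 * (self.nu[k] - np.arange(self.p))))
                - self.p * np.log(2.0)
            )
            diff = obs - means[k]
            maha = np.einsum("ti,ij,tj->t", diff, prec, diff)
            out[:, k] = -0.5 * (self.p * _LOG2PI + e_logdet_sigma + maha)
        return out

    def kl(self) -> float:
        kl = _dirichlet_kl(self.alpha_pi, self.alpha_pi0)
        kl += _dirichlet_kl(self.alpha_a, self.alpha_a0)
        for k in range(self.k):
            kl += _inverse_wishart_kl(self.nu[k], self.s[k], self.nu0, self.s0)
        return kl

    def m_step(self, obs: np.ndarray, gamma: np.ndarray, xi: np.ndarray,
               start_gamma: np.ndarray, means: np.ndarray) -> None:
        self.alpha_pi = self.alpha_pi0 + start_gamma
        self.alpha_a = self.alpha_a0 + xi
        for k in range(self.k):
            w = gamma[:, k]
            diff = obs - means[k]
            scatter = (diff * w[:, None]).T @ diff
            self.nu[k] = self.nu0 + w.sum()
            self.s[k] = self.s0 + scatter

    def point_params(self, means: np.ndarray, reg: float) -> HMMParams:
        pi = self.alpha_pi / self.alpha_pi.sum()
        a = self.alpha_a / self.alpha_a.sum(axis=1, keepdims=True)
        covs = np.empty_like(self.s)
        for k in range(self.k):
            denom = self.nu[k] - self.p - 1.0
            cov = self.s[k] / max(denom, 1.0)
            cov = cov + reg * np.trace(cov) / max(self.p, 1) * np.eye(self.p)
            covs[k] = 0.5 * (cov + cov.T)
        return HMMParams(pi=pi, transition=a, means=means.copy(),
                         covariances=covs, dirichlet_alpha=float(self.alpha_a0[0, 0]),
                         wishart_dof=float(self.nu0))


def fit_vb(
    data: np.ndarray,
    k: int,
    boundaries: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> tuple[HMMParams, StateTimeCourse]:
    """Fit a K-state Gaussian HMM by variational EM.

    ``data`` is P x T (components x concatenated samples); ``boundaries``
    holds each subject's start offset so chains restart between subjects.
    Runs ``n_restarts`` restarts from random per-sample Dirichlet posteriors
    and returns the restart with the lowest final free energy.  When
    ``options.minibatch`` is set, each iteration performs a stochastic
    natural-gradient update on a random subject subset (step size
    ``(iter + delay)^-forget``) instead of a full-batch update; the free
    energy trace is then a noisy estimate and not guaranteed monotone.

    Returns posterior-mean point parameters and the final state time course.
    """
    opts = options or FitOptions()
    obs = np.asarray(data, dtype=float).T  # (T, P)
    t_n, p = obs.shape
    if k < 1:
        raise ValueError(f"number of states must be >= 1, got {k}")
    if t_n == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(opts.seed)
    data_var = float(obs.var(axis=0).mean())
    segs = _segments(t_n, boundaries)

    best: tuple[float, HMMParams, StateTimeCourse] | None = None
    for _restart in range(max(1, opts.n_restarts)):
        vb = _VBState(k, p, opts, data_var)
        means = np.zeros((k, p))
        if opts.init == "blocks" and k > 1:
            # assign contiguous windows wholly to random states so the
            # initial covariances differ; softened to keep gamma interior
            labels = rng.integers(k, size=(t_n // opts.init_block_len) + 1)
            hard = np.repeat(labels, opts.init_block_len)[:t_n]
            gamma = np.full((t_n, k), 0.1 / max(k - 1, 1))
            gamma[np.arange(t_n), hard] = 0.9
        else:
            gamma = rng.dirichlet(np.ones(k), size=t_n)
        xi0 = np.zeros((k, k))
        for s, e in segs:
            g = gamma[s:e]
            xi0 += g[:-1].T @ g[1:]
        start_gamma = np.sum([gamma[s] for s, _ in segs], axis=0)
        if opts.learn_means:
            means = _update_means(obs, gamma)
        vb.m_step(obs, gamma, xi0, start_gamma, means)

        trace = []
        converged = False
        if opts.minibatch is not None and boundaries is not None and len(segs) > 1:
            trace = _fit_stochastic(vb, obs, segs, opts, rng, means)
        else:
            prev_f = np.inf
            for _it in range(opts.max_iter):
                log_b = vb.expected_log_b(obs, means)
                gamma, xi, loglik = _forward_backward_core(
                    log_b, vb.expected_log_pi(), vb.expected_log_a(), boundaries
                )
                f = -loglik + vb.kl()
                trace.append(f)
                if abs(prev_f - f) <= opts.tol * (1.0 + abs(f)):
                    converged = True
                start_gamma = np.sum([gamma[s] for s, _ in segs], axis=0)
                if opts.learn_means:
                    means = _update_means(obs, gamma)
                vb.m_step(obs, gamma, xi, start_gamma, means)
                if converged:
                    break
                prev_f = f
            if not converged:
                import warnings

                warnings.warn(
                    f"variational fit did not converge within {opts.max_iter} "
                    "iterations", RuntimeWarning, stacklevel=2,
                )

        params = vb.point_params(means, opts.reg)
        log_b = vb.expected_log_b(obs, means)
        gamma, xi, loglik = _forward_backward_core(
            log_b, vb.expected_log_pi(), vb.expected_log_a(), boundaries
        )
        final_f = -loglik + vb.kl()
        trace.append(final_f)
        params.free_energy = final_f
        course = StateTimeCourse(
            gamma=gamma, xi=xi, subject_boundaries=boundaries,
            log_likelihood=loglik, free_energy_trace=np.asarray(trace),
        )
        if best is None or final_f < best[0]:
            best = (final_f, params, course)
    assert best is not None
    return best[1], best[2]


def _update_means(obs: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    w = gamma.sum(axis=0)
    w[w == 0] = 1.0
    return (gamma.T @ obs) / w[:, None]


def _fit_stochastic(vb: _VBState, obs: np.ndarray, segs, opts: FitOptions,
                    rng: np.random.Generator, means: np.ndarray) -> list[float]:
    """Stochastic VB: per iteration, E-step on a random subject subset and a
    decaying-step natural-parameter update scaled to the full data size."""
    n_subj = len(segs)
    batch = min(opts.minibatch or n_subj, n_subj)
    scale = n_subj / batch
    trace: list[float] = []
    for it in range(opts.max_iter):
        rho = (it + opts.minibatch_delay) ** (-opts.minibatch_forget)
        pick = rng.choice(n_subj, size=batch, replace=False)
        idx = np.concatenate([np.arange(s, e) for j in pick for s, e in [segs[j]]])
        sub = obs[idx]
        sub_bounds = np.concatenate(
            ([0], np.cumsum([segs[j][1] - segs[j][0] for j in pick])[:-1])
        )
        log_b = vb.expected_log_b(sub, means)
        gamma, xi, loglik = _forward_backward_core(
            log_b, vb.expected_log_pi(), vb.expected_log_a(), sub_bounds
        )
        trace.append(-loglik * scale + vb.kl())
        start_gamma = gamma[sub_bounds].sum(axis=0)
        # interpolate natural parameters toward the rescaled batch statistics
        vb.alpha_pi = (1 - rho) * vb.alpha_pi + rho * (vb.alpha_pi0 + scale * start_gamma)
        vb.alpha_a = (1 - rho) * vb.alpha_a + rho * (vb.alpha_a0 + scale * xi)
        for k in range(vb.k):
            w = gamma[:, k]
            diff = sub - means[k]
            scatter = (diff * w[:, None]).T @ diff
            vb.nu[k] = (1 - rho) * vb.nu[k] + rho * (vb.nu0 + scale * w.sum())
            vb.s[k] = (1 - rho) * vb.s[k] + rho * (vb.s0 + scale * scatter)
    return trace


def _spd_logm(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * np.log(vals)) @ vecs.T


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between SPD matrices:
    || log(A^{-1/2} B A^{-1/2}) ||_F."""
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, 1e-12, None)
    inv_sqrt = (vecs / np.sqrt(vals)) @ vecs.T
    mid = inv_sqrt @ b @ inv_sqrt
    return float(np.linalg.norm(_spd_logm(0.5 * (mid + mid.T))))


def align_states(reference: HMMParams, other: HMMParams) -> np.ndarray:
    """Permutation aligning ``other``'s states to ``reference``'s.

    Similarity is based on the affine-invariant (Riemannian) geometry of the
    state covariances; the optimal assignment minimizes the total distance.
    ``perm[j]`` gives the reference state matched to ``other``'s state ``j``,
    i.e. ``other.covariances[j]`` corresponds to
    ``reference.covariances[perm[j]]``.
    """
    if reference.n_states != other.n_states:
        raise ValueError(
            f"state counts differ: {reference.n_states} vs {other.n_states}"
        )
    k = reference.n_states
    cost = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = riemannian_distance(
                reference.covariances[i], other.covariances[j]
            )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows
    return perm
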