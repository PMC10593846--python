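"""HMM inference: exact-oracle checks, variational fitting, state alignment."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import tdehmm as t
from tdehmm.hmm import riemannian_distance


def random_instance(rng, t_max=8, k_max=3, p=2):
    """Random small HMM instance with point parameters and observations."""
    k = int(rng.integers(1, k_max + 1))
    n = int(rng.integers(2, t_max + 1))
    pi = rng.dirichlet(np.ones(k))
    a = rng.dirichlet(np.ones(k), size=k)
    means = rng.normal(size=(k, p))
    covs = np.empty((k, p, p))
    for i in range(k):
        m = rng.normal(size=(p, p))
        covs[i] = m @ m.T + 0.5 * np.eye(p)
    params = t.HMMParams(pi=pi, transition=a, means=means, covariances=covs)
    obs = rng.normal(size=(n, p))
    return params, obs


def brute_force_posteriors(params, obs):
    """Enumerate all K^T paths: exact gamma, log-likelihood, and MAP path
    (ties broken toward the lexicographically smallest path)."""
    k, n = params.n_states, obs.shape[0]
    log_b = np.array(
        [
            [
                multivariate_normal.logpdf(obs[i], params.means[s],
                                           params.covariances[s])
                for s in range(k)
            ]
            for i in range(n)
        ]
    )
    log_joint = {}
    for path in itertools.product(range(k), repeat=n):
        lp = np.log(params.pi[path[0]]) + log_b[0, path[0]]
        for i in range(1, n):
            lp += np.log(params.transition[path[i - 1], path[i]]) + log_b[i, path[i]]
        log_joint[path] = lp
    total = np.logaddexp.reduce(list(log_joint.values()))
    gamma = np.zeros((n, k))
    for path, lp in log_joint.items():
        w = np.exp(lp - total)
        for i, s in enumerate(path):
            gamma[i, s] += w
    map_path = min(log_joint, key=lambda p: (-log_joint[p], p))
    return gamma, total, np.array(map_path)


class TestExactInference:
    def test_forward_backward_matches_enumeration(self):
        rng = np.random.default_rng(100)
        for _ in range(30):
            params, obs = random_instance(rng)
            course = t.forward_backward(params, obs)
            gamma, total, _ = brute_force_posteriors(params, obs)
            assert np.allclose(course.gamma, gamma, atol=1e-12)
            assert abs(course.log_likelihood - total) < 1e-10

    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(200)
        for _ in range(30):
            params, obs = random_instance(rng)
            path = t.viterbi(params, obs)
            _, _, map_path = brute_force_posteriors(params, obs)
            assert np.array_equal(path, map_path)

    def test_three_sample_two_state_fixed_instance(self):
        # hand-fixed instance; oracle sums over all 8 paths
        params = t.HMMParams(
            pi=np.array([0.6, 0.4]),
            transition=np.array([[0.9, 0.1], [0.3, 0.7]]),
            means=np.array([[0.0], [2.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
        )
        obs = np.array([[0.1], [1.9], [2.2]])
        course = t.forward_backward(params, obs)
        gamma, total, _ = brute_force_posteriors(params, obs)
        assert np.allclose(course.gamma, gamma, atol=1e-12)

    def test_single_state_gamma_is_one_and_loglik_is_gaussian_sum(self, rng):
        obs = rng.normal(size=(50, 3))
        cov = np.eye(3) * 2.0
        params = t.HMMParams(
            pi=np.array([1.0]), transition=np.array([[1.0]]),
            means=np.zeros((1, 3)), covariances=cov[None],
        )
        course = t.forward_backward(params, obs)
        assert np.allclose(course.gamma, 1.0)
        expected = multivariate_normal.logpdf(obs, np.zeros(3), cov).sum()
        assert abs(course.log_likelihood - expected) < 1e-8
        assert np.all(t.viterbi(params, obs) == 0)

    def test_symmetric_model_gives_uniform_gamma(self, rng):
        k = 3
        obs = rng.normal(size=(40, 2))
        params = t.HMMParams(
            pi=np.full(k, 1 / k), transition=np.full((k, k), 1 / k),
            means=np.zeros((k, 2)), covariances=np.tile(np.eye(2), (k, 1, 1)),
        )
        course = t.forward_backward(params, obs)
        assert np.allclose(course.gamma, 1 / k, atol=1e-12)

    def test_dominant_likelihood_viterbi_is_argmax(self, rng):
        # near-uniform transitions + far-apart states: path = per-sample argmax
        k = 3
        means = np.array([[0.0], [50.0], [100.0]])
        covs = np.tile(np.eye(1) * 0.1, (k, 1, 1))
        params = t.HMMParams(
            pi=np.full(k, 1 / k),
            transition=np.full((k, k), 1 / k),
            means=means, covariances=covs,
        )
        labels = rng.integers(k, size=100)
        obs = means[labels] + rng.normal(0, 0.1, size=(100, 1))
        assert np.array_equal(t.viterbi(params, obs), labels)


class TestVariationalFit:
    def test_single_state_covariance_matches_sample_covariance(self, rng):
        obs = rng.normal(size=(5, 2000)) * np.array([[1.0], [2.0], [0.5], [1.5], [3.0]])
        params, course = t.fit_vb(obs, 1, options=t.FitOptions(n_restarts=1, max_iter=5))
        sample_cov = np.cov(obs, bias=True)
        # prior-weighted estimate: close to the sample covariance at T=2000
        assert np.allclose(params.covariances[0], sample_cov, rtol=0.05, atol=0.05)
        assert np.allclose(course.gamma, 1.0)

    def test_same_seed_gives_identical_free_energy(self, rng):
        obs = rng.normal(size=(3, 800))
        opts = t.FitOptions(n_restarts=2, max_iter=10, seed=5)
        p1, c1 = t.fit_vb(obs, 2, options=opts)
        p2, c2 = t.fit_vb(obs, 2, options=opts)
        assert p1.free_energy == p2.free_energy
        assert np.array_equal(c1.gamma, c2.gamma)

    def test_free_energy_trace_non_increasing(self, rng):
        obs = rng.normal(size=(4, 2000))
        obs[:2, :1000] *= 3.0
        _, course = t.fit_vb(
            obs, 2, options=t.FitOptions(n_restarts=1, max_iter=25, seed=1)
        )
        fe = course.free_energy_trace
        assert np.all(np.diff(fe) <= 1e-6 * np.abs(fe[:-1]) + 1e-9)

    def test_fit_invariants_hold(self, rng):
        obs = rng.normal(size=(3, 1500))
        params, course = t.fit_vb(
            obs, 3, options=t.FitOptions(n_restarts=1, max_iter=10, seed=2)
        )
        assert np.allclose(course.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(params.transition.sum(axis=1), 1.0, atol=1e-10)
        for cov in params.covariances:
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_invalid_k_and_empty_data_rejected(self):
        with pytest.raises(ValueError):
            t.fit_vb(np.zeros((2, 100)), 0)
        with pytest.raises(ValueError):
            t.fit_vb(np.zeros((2, 0)), 2)

    def test_nonconvergence_warns(self, rng):
        obs = rng.normal(size=(3, 500))
        with pytest.warns(RuntimeWarning, match="converge"):
            t.fit_vb(obs, 2, options=t.FitOptions(n_restarts=1, max_iter=2, seed=0))

    def test_accuracy_improves_with_data_length(self):
        # 2-state covariance-switching data: more samples, better recovery
        import itertools as it

        def run(n_samples, seed):
            rng = np.random.default_rng(seed)
            half = n_samples // 2
            labels = np.zeros(n_samples, dtype=int)
            # sticky alternation in blocks of 200
            state, pos = 0, 0
            while pos < n_samples:
                run_len = int(rng.geometric(0.01))
                labels[pos: pos + run_len] = state
                state = 1 - state
                pos += run_len
            scale = np.where(labels == 0, 1.0, 3.0)
            obs = (rng.normal(size=(2, n_samples)) * scale).astype(float)
            params, course = t.fit_vb(
                obs, 2, options=t.FitOptions(n_restarts=1, max_iter=15, seed=seed)
            )
            hard = course.hard_path()
            return max(np.mean(hard == labels), np.mean(hard == 1 - labels))

        accs_small = [run(2000, s) for s in range(3)]
        accs_large = [run(20000, s) for s in range(3)]
        assert np.mean(accs_large) >= np.mean(accs_small) - 0.02


class TestStateAlignment:
    def _params(self, covs):
        k = len(covs)
        return t.HMMParams(
            pi=np.full(k, 1 / k), transition=np.full((k, k), 1 / k),
            means=np.zeros((k, covs[0].shape[0])), covariances=np.asarray(covs),
        )

    def test_identity_for_identical_models(self, rng):
        covs = [np.diag([1.0, 2.0]), np.diag([3.0, 0.5]), np.diag([5.0, 5.0])]
        ref = self._params(covs)
        assert np.array_equal(t.align_states(ref, ref), [0, 1, 2])

    def test_reversed_states_give_reversing_permutation(self):
        covs = [np.diag([1.0, 2.0]), np.diag([3.0, 0.5]), np.diag([5.0, 5.0])]
        ref = self._params(covs)
        other = self._params(covs[::-1])
        assert np.array_equal(t.align_states(ref, other), [2, 1, 0])

    def test_noisy_copies_matched_correctly(self, rng):
        base = [np.diag([1.0, 4.0]), np.diag([4.0, 1.0]), np.eye(2) * 2.5]
        noisy = []
        order = [1, 2, 0]
        for i in order:
            jitter = rng.normal(scale=0.05, size=(2, 2))
            noisy.append(base[i] + jitter @ jitter.T)
        perm = t.align_states(self._params(base), self._params(noisy))
        assert np.array_equal(perm, order)

    def test_mismatched_state_count_rejected(self):
        a = self._params([np.eye(2), np.eye(2) * 2])
        b = self._params([np.eye(2)])
        with pytest.raises(ValueError):
            t.align_states(a, b)

    def test_riemannian_distance_is_affine_invariant(self, rng):
        a = np.diag([1.0, 3.0])
        b = np.diag([2.0, 0.5])
        m = rng.normal(size=(2, 2))
        g = m @ m.T + 2 * np.eye(2)
        # congruence by any invertible matrix preserves the distance
        l = np.linalg.cholesky(g)
        d1 = riemannian_distance(a, b)
        d2 = riemannian_distance(l @ a @ l.T, l @ b @ l.T)
        assert abs(d1 - d2) < 1e-8
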