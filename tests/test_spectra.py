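"""State-weighted multitaper spectra, NNMF modes, projections, GMM thresholds."""

import numpy as np
import pytest

import tdehmm as t


def _rec(data, fs=250.0):
    data = np.asarray(data, dtype=float)
    return t.Recording(data=data, fs=fs,
                       region_names=[f"r{i}" for i in range(data.shape[0])])


def _uniform_course(n, k=1):
    return t.StateTimeCourse(gamma=np.full((n, k), 1.0 / k))


class TestWeightedMultitaper:
    def test_single_active_state_equals_unweighted_estimate(self, rng):
        data = rng.normal(size=(3, 5000))
        rec = _rec(data)
        est1 = t.weighted_multitaper(rec, _uniform_course(5000, 1))
        # two states, one always active: the active state's spectrum matches
        gamma = np.zeros((5000, 2))
        gamma[:, 1] = 1.0
        with pytest.warns(RuntimeWarning, match="zero total weight"):
            est2 = t.weighted_multitaper(
                rec, t.StateTimeCourse(gamma=gamma)
            )
        assert np.allclose(est2.psd[1], est1.psd[0], atol=1e-10)
        assert 0 in est2.missing_states
        assert np.isnan(est2.psd[0]).all()

    def test_sinusoid_peak_at_nearest_grid_frequency(self, rng):
        n = 10000
        x = np.sin(2 * np.pi * 10.0 * np.arange(n) / 250.0)
        data = np.vstack([x + 0.01 * rng.normal(size=n),
                          0.01 * rng.normal(size=n)])
        est = t.weighted_multitaper(_rec(data), _uniform_course(n))
        peak = est.freqs[np.argmax(est.psd[0][:, 0])]
        assert abs(peak - 10.0) <= 0.5

    def test_identical_channels_have_unit_coherence(self, rng):
        x = rng.normal(size=4000)
        est = t.weighted_multitaper(_rec(np.vstack([x, x])),
                                    _uniform_course(4000))
        assert np.allclose(est.coherence[0][:, 0, 1], 1.0, atol=1e-6)

    def test_independent_noise_coherence_below_analytic_floor(self, rng):
        n = 50000
        data = rng.normal(size=(2, n))
        est = t.weighted_multitaper(_rec(data), _uniform_course(n))
        opts = est.options
        win = int(opts.window_s * 250)
        n_windows = 1 + (n - win) // (win // 2)
        # mean coherence of independent noise ~ sqrt(pi/4 / dof); generous
        # bound at 3x the sqrt(1/dof) scale of the estimator noise floor
        dof = n_windows * opts.n_tapers
        floor = 3.0 / np.sqrt(dof)
        assert est.coherence[0][:, 0, 1].mean() < floor

    def test_coherence_invariants(self, benchmark_fit):
        course = t.StateTimeCourse(
            gamma=benchmark_fit["course"].gamma,
            sample_indices=benchmark_fit["index_map"],
        )
        est = t.weighted_multitaper(benchmark_fit["recording"], course)
        coh = est.coherence
        assert np.nanmin(coh) >= 0.0 and np.nanmax(coh) <= 1.0
        assert np.allclose(coh, np.swapaxes(coh, 2, 3), equal_nan=True)
        ii = np.arange(est.n_regions)
        assert np.allclose(coh[:, :, ii, ii], 1.0)
        assert np.nanmin(est.psd) >= 0.0

    def test_mixture_decomposition_consistency(self, rng):
        # sum over states of weight x state spectrum ~ unweighted spectrum
        n = 20000
        data = rng.normal(size=(2, n))
        gamma = rng.dirichlet(np.ones(3), size=n)
        est = t.weighted_multitaper(_rec(data), t.StateTimeCourse(gamma=gamma))
        unweighted = t.weighted_multitaper(_rec(data), _uniform_course(n))
        mix = np.einsum("k,kfr->fr", est.state_weights, est.psd)
        assert np.allclose(mix, unweighted.psd[0], rtol=0.2, atol=0.05)


class TestNNMFModes:
    def test_exact_rank2_factorization_recovered(self, rng):
        w = np.abs(rng.normal(size=(30, 2)))
        h = np.abs(rng.normal(size=(2, 50)))
        matrix = w @ h
        modes = t.nnmf_modes(matrix, n_modes=2, n_restarts=3, max_iter=5000,
                             tol=1e-12, seed=0)
        rel = modes.residual / np.linalg.norm(matrix)
        assert rel < 1e-6

    def test_disjoint_bands_recovered_band_confined(self, rng):
        freqs = np.linspace(1, 40, 79)
        theta = np.exp(-0.5 * ((freqs - 6) / 1.0) ** 2)
        alpha = np.exp(-0.5 * ((freqs - 10) / 1.0) ** 2)
        theta[freqs > 8] = 0.0
        alpha[(freqs < 8) | (freqs > 12)] = 0.0
        cols = []
        for _ in range(40):
            cols.append(rng.uniform(0.5, 2.0) * theta + 0.01 * rng.random(79))
            cols.append(rng.uniform(0.5, 2.0) * alpha + 0.01 * rng.random(79))
        matrix = np.array(cols).T
        modes = t.nnmf_modes(matrix, n_modes=2, seed=1, freqs=freqs)
        low = modes.profiles[:, 0]
        high = modes.profiles[:, 1]
        assert low[freqs <= 8].sum() / low.sum() >= 0.9
        assert high[(freqs >= 8) & (freqs <= 12)].sum() / high.sum() >= 0.9

    def test_single_mode_residual_dominates_two_modes(self, rng):
        matrix = np.abs(rng.normal(size=(20, 30)))
        r1 = t.nnmf_modes(matrix, n_modes=1, seed=0).residual
        r2 = t.nnmf_modes(matrix, n_modes=2, seed=0).residual
        assert r1 >= r2

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            t.nnmf_modes(np.array([[1.0, -0.1], [0.2, 0.3]]), n_modes=1)

    def test_modes_ordered_by_peak_frequency(self, rng):
        freqs = np.linspace(1, 40, 79)
        profiles = [np.exp(-0.5 * ((freqs - f) / 1.5) ** 2) for f in (25, 6, 12)]
        h = np.abs(rng.normal(size=(3, 60)))
        matrix = np.array(profiles).T @ h
        modes = t.nnmf_modes(matrix, n_modes=3, seed=2, freqs=freqs)
        peaks = [freqs[np.argmax(modes.profiles[:, m])] for m in range(3)]
        assert peaks == sorted(peaks)


class TestProjection:
    def _estimate(self, psd, coh, freqs):
        return t.SpectralEstimate(
            freqs=freqs, psd=psd, coherence=coh,
            state_weights=np.ones(psd.shape[0]) / psd.shape[0],
            options=t.MultitaperOptions(),
        )

    def test_delta_mode_projection_picks_single_bin(self, rng):
        freqs = np.linspace(1, 40, 40)
        psd = rng.random((1, 40, 3))
        coh = np.ones((1, 40, 3, 3))
        est = self._estimate(psd, coh, freqs)
        profiles = np.zeros((40, 1))
        profiles[7, 0] = 1.0
        modes = t.SpectralModes(freqs=freqs, profiles=profiles,
                                loadings=np.zeros((1, 1)), residual=0.0,
                                n_psd_features=3)
        maps, coh_proj = t.project_and_zscore([est], modes)
        raw = psd[0, 7, :]
        expected = (raw - raw.mean()) / raw.std()
        assert np.allclose(maps[0, 0], expected)

    def test_uniform_psd_zscores_to_zero(self):
        freqs = np.linspace(1, 40, 40)
        psd = np.ones((1, 40, 4))
        coh = np.ones((1, 40, 4, 4))
        est = self._estimate(psd, coh, freqs)
        modes = t.SpectralModes(freqs=freqs, profiles=np.ones((40, 1)),
                                loadings=np.zeros((1, 1)), residual=0.0,
                                n_psd_features=4)
        maps, _ = t.project_and_zscore([est], modes)
        assert np.allclose(maps, 0.0)

    def test_band_specific_states_order_on_matching_modes(self):
        freqs = np.linspace(1, 40, 79)
        low = np.exp(-0.5 * ((freqs - 6) / 1.5) ** 2)
        high = np.exp(-0.5 * ((freqs - 10) / 1.5) ** 2)
        psd = np.zeros((2, 79, 2))
        psd[0, :, 0] = low      # theta state, region 0
        psd[1, :, 0] = high     # alpha state, region 0
        coh = np.tile(np.eye(2), (2, 79, 1, 1))
        coh[0, :, 0, 1] = coh[0, :, 1, 0] = low
        coh[1, :, 0, 1] = coh[1, :, 1, 0] = high
        est = self._estimate(psd, coh, freqs)
        modes = t.SpectralModes(freqs=freqs,
                                profiles=np.column_stack([low, high]),
                                loadings=np.zeros((2, 1)), residual=0.0,
                                n_psd_features=2)
        _, coh_proj = t.project_and_zscore([est], modes)
        # theta state scores higher on the low mode; alpha on the high mode
        assert coh_proj[0, 0, 0, 1] > coh_proj[1, 0, 0, 1]
        assert coh_proj[1, 1, 0, 1] > coh_proj[0, 1, 0, 1]


class TestGMMThreshold:
    def test_separable_mixture_keeps_exactly_high_cluster(self, rng):
        low = rng.normal(0.1, 0.01, size=761)
        high = rng.normal(0.6, 0.01, size=100)
        values = np.concatenate([low, high])
        net = t.gmm_threshold(values, seed=0)
        kept_vals = np.array([v for _, _, v in net.kept])
        assert len(net.kept) == 100
        assert kept_vals.min() > 0.3
        assert not net.fallback

    def test_fitted_means_recovered(self, rng):
        low = rng.normal(0.1, 0.05, size=700)
        high = rng.normal(0.6, 0.05, size=161)
        net = t.gmm_threshold(np.concatenate([low, high]), seed=1)
        means = np.sort(net.means)
        assert abs(means[0] - 0.1) < 0.02
        assert abs(means[1] - 0.6) < 0.02

    def test_degenerate_equal_values_trigger_fallback(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            net = t.gmm_threshold(np.full(50, 0.3))
        assert net.fallback
        assert net.kept == []

    def test_kept_values_respect_threshold(self, rng):
        values = np.concatenate([rng.normal(0.2, 0.05, 400),
                                 rng.normal(0.7, 0.05, 80)])
        net = t.gmm_threshold(values, seed=2)
        for _, _, v in net.kept:
            assert v >= net.threshold

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            t.gmm_threshold(np.array([0.1, 0.2, 0.3]))
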