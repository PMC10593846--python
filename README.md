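# tdehmm

Transient, spectrally resolved network states in multichannel
electrophysiological recordings.

Parcellated M/EEG source time series switch on a sub-second timescale between
recurring large-scale networks — frequency-specific patterns of power and
phase-coupling across brain regions. `tdehmm` decomposes such recordings into
K hidden network states and characterizes each state in time (when it
activates relative to task events), space (where its power concentrates) and
frequency (which rhythm carries its coupling). The package is aimed at
cognitive/clinical neurophysiology groups analysing task recordings (e.g. an
n-back working-memory session), and ships a ground-truthed simulator of
Markov-switching oscillatory networks so the entire pipeline can be validated
without access to restricted patient data.

## Method

1. **Leakage correction** — multivariate symmetric orthogonalization: the
   closest (Frobenius) matrix with mutually orthogonal rows, removing
   zero-lag source-leakage correlations without preferring any region.
2. **Time-delay embedding + PCA** — each region is stacked with its lagged
   copies (default lags −7…+7, a 60 ms window at 250 Hz) and the stacked
   matrix is reduced to P principal components (default 2 × regions), so a
   state's covariance Σ_k encodes frequency-resolved power and cross-region
   phase-coupling.
3. **Gaussian HMM by variational Bayes** — observations x_t | s_t = k ~
   N(0, Σ_k) with a sticky Markov chain over states; conjugate priors
   (Dirichlet on transition rows, inverse-Wishart on Σ_k) give a closed-form
   variational EM whose free energy decreases monotonically. Posterior state
   probabilities γ_tk come from the forward–backward recursions, hard paths
   from Viterbi; multiple restarts are scored by final free energy and
   states of different runs are aligned by Riemannian matching of their
   covariances.
4. **Temporal metrics & evoked analysis** — fractional occupancy, lifetimes
   and interval times; γ epoched on [−0.2, 1.2] s around stimulus onsets with
   a [−200, −30] ms baseline; a two-level GLM (constant + six demeaned
   condition regressors; target-vs-distractor and memory-load contrasts)
   tested with sign-flip permutations and maximum statistics across states
   and time (two-sided, p < 0.025 per tail).
5. **Spectral profiles** — multitaper cross-spectra of the recording weighted
   by each state's γ give per-state PSD and coherence in 1–40 Hz; pooled
   spectra are factorized by non-negative matrix factorization into
   data-driven frequency modes; mode-projected PSD maps are z-scored across
   regions and coherence networks are thresholded with a two-component
   Gaussian mixture to keep only the strong connections.

## Worked example

Simulate one subject with three oscillatory networks (6, 10 and 20 Hz on
disjoint region triplets, self-transition probability 0.98), fit the model,
and compare against the known ground truth:

```python
import numpy as np, itertools
import tdehmm as t

specs = (
    t.StateSpec(regions=(0, 1, 2), freq_hz=6.0, amplitude=2.0),
    t.StateSpec(regions=(3, 4, 5), freq_hz=10.0, amplitude=2.0),
    t.StateSpec(regions=(6, 7, 8), freq_hz=20.0, amplitude=2.0),
)
cfg = t.SimConfig(n_regions=10, fs=250.0, n_states=3, stickiness=0.98,
                  state_specs=specs, noise_sd=1.0, duration_s=120.0, seed=0)
truth = t.simulate_state_path(cfg)
rec = t.render_recording(truth, cfg)

reduced, bounds, maps, pca = t.preprocess_group([rec], t.EmbeddingSpec(),
                                                orthogonalize=False)
params, course = t.fit_vb(reduced, 3, boundaries=bounds,
                          options=t.FitOptions(n_restarts=2, max_iter=50, seed=1))

stats = t.temporal_stats(course, fs=cfg.fs)
print(stats.to_frame().to_string(index=False))
print("self-transitions:", np.diag(params.transition).round(3))
acc = max(np.mean(np.asarray(p)[course.hard_path()]
                  == truth.state_path[maps[0]])
          for p in itertools.permutations(range(3)))
print(f"state-path accuracy vs ground truth: {acc:.3f}")
```

prints

```
 state       FO      LT_ms      IT_ms
     0 0.337524 224.911111 436.670391
     1 0.331855 242.707317 490.233129
     2 0.330621 238.891566 486.181818
self-transitions: [0.982 0.983 0.983]
state-path accuracy vs ground truth: 0.962
```

Each state occupies about a third of the recording (`FO`), stays active for
~230 ms per visit (`LT_ms`, consistent with the 0.98 self-transition
probability: 50 samples × 4 ms), and the fitted self-transitions land within
0.005 of the generating value; 96% of samples are assigned to the correct
ground-truth state after alignment. Weighting a multitaper estimate by the
fitted state probabilities recovers each network's spectral peak at its
generating frequency.

The same stages are available from the shell:

```sh
tdehmm simulate --out data/ --seed 1 --n-regions 42 --n-states 6 --duration 730
tdehmm fit data/recording.h5 --k 6 --restarts 5 --seed 2 --out fit/
tdehmm metrics fit/gamma.h5 --fs 250 --out stats.tsv
tdehmm run-all --seed 3 --out run/
```

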