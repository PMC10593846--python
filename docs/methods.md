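# Methods

## Model

The observed recording Y (regions × samples, sampling rate `fs`) is treated
as arising from the alternating activation of K hidden network states. After
preprocessing, the model is a hidden Markov chain s_t ∈ {1…K} with initial
distribution π, row-stochastic transition matrix A, and Gaussian emissions
x_t | s_t = k ~ N(μ_k, Σ_k) on the reduced embedded data x_t ∈ R^P. Means
are fixed at zero by default: after per-region z-scoring the embedded data
are zero-mean, and all state identity is carried by the covariance Σ_k,
which — because x_t stacks lagged copies of every region — encodes each
state's frequency-resolved power and cross-region phase-coupling. A flag
(`FitOptions.learn_means`) frees the means for data where DC shifts matter.

Mutual exclusivity is a modelling assumption: exactly one state is "active"
per sample. Overlapping network activations are not representable; they
surface as rapid switching or as mixed posterior probabilities.

## Preprocessing

* **Symmetric orthogonalization.** The demeaned data matrix X is replaced by
  the closest (Frobenius) matrix with mutually orthogonal rows — the
  orthonormal polar factor U Vᵀ of the SVD X = U S Vᵀ — rescaled so each row
  keeps its norm. This removes all zero-lag correlations (volume-conduction
  leakage) and treats every region symmetrically: permuting regions commutes
  with the operation. Rank-deficient input (e.g. duplicated regions) is
  rejected with an explicit rank error rather than silently regularized.
* **Embedding.** Default lags −7…+7 (15 copies, a 60 ms window at 250 Hz,
  tuned to the sub-25 Hz rhythms the analysis targets). The max-|lag|
  samples at each edge are dropped, never padded; an index map records the
  surviving original sample indices so event onsets stay aligned downstream.
* **PCA.** Fit once on the embedded data concatenated across subjects
  (group PCA, matching group-level inference), after per-subject per-region
  z-scoring. Default P = 2 × regions. Scores are not whitened: the HMM
  states are defined by covariance structure, which whitening would erase.
  Standardizing the scores is exposed as a flag, default off.

## Variational inference

Conjugate priors: symmetric Dirichlet (concentration 1) on each row of A and
on π; inverse-Wishart on each Σ_k with ν₀ = P + 2 degrees of freedom and
scale S₀ = 10⁻³ · (mean data variance) · ν₀ · I — weak enough that with
10³–10⁵ samples per state the likelihood dominates, strong enough to keep
every posterior scale matrix positive-definite. Variational EM alternates:

* **E-step**: forward–backward with the expected-log parameters
  exp E[log A], exp E[log π] and the expected Gaussian log-density
  (E[Σ_k⁻¹] = ν_k S_k⁻¹ and the Wishart expectation of log det Σ_k),
  implemented with per-sample scaling; the scaling constants accumulate to
  the evidence term of the free energy.
* **M-step**: closed-form conjugate updates of the Dirichlet counts and the
  inverse-Wishart (ν_k, S_k) from γ and the summed transition posteriors ξ.

The free energy −log Z̃ + KL(q‖prior) is evaluated every iteration and is
monotonically non-increasing for full-batch updates (asserted in the tests
to 10⁻⁶ relative). Point estimates reported after fitting are posterior
means; covariances additionally receive a 10⁻⁶ × mean-diagonal ridge before
any inversion elsewhere.

**Initialization.** Contiguous blocks of 100 samples are assigned wholly to
random states (softened to γ = 0.9), so initial covariance estimates differ
across states. Purely per-sample Dirichlet initialization (also available)
starts all states at nearly the same covariance and, on strongly sticky
oscillatory data, reliably converges to a local optimum in which one state
absorbs transition periods and two spectral states merge. `n_restarts`
(default 5) independent initializations are run and the lowest final free
energy wins; replicate runs can be compared with `align_states`, which
matches states across runs by minimum affine-invariant Riemannian distance
between covariances via optimal assignment.

**Stochastic option.** `FitOptions.minibatch` enables a stochastic
natural-gradient variant (random subject subsets per iteration, step size
(t + 2)^−0.6, statistics rescaled to the full data size) for cohorts too
large for full-batch passes. It is an efficiency device, not part of the
model; desk-scale data default to full batch, where the monotonicity
guarantee holds.

**Viterbi** decodes the MAP path in log space; ties break toward the lower
state index for determinism.

## Temporal metrics and evoked analysis

States are binarized by per-sample argmax of γ, making fractional occupancy
an exact partition (FO sums to 1). A probability-threshold binarization is
available (`gamma_threshold`), under which occupancies are raw fractions and
need not sum to 1. Lifetimes are contiguous-visit durations, interval times
the gaps between visits, both in ms; a state never visited reports NaN, not
zero. Epochs span [−0.2, 1.2] s around each onset (351 samples at 250 Hz)
with the baseline mean taken over [−200, −30] ms; window edges round to the
nearest sample (−30 ms at 250 Hz rounds to sample −8, i.e. −32 ms). Onsets
are mapped through the embedding's index map, so the dropped edges cannot
shift latencies. Trials that do not fit entirely inside the recording are
dropped and counted.

## Two-level GLM

First level, per subject and per (state, timepoint): OLS of trialwise
baseline-corrected occupancy on a constant plus the six demeaned condition
indicators. The six demeaned indicators sum to the zero vector, so the
design matrix has rank 6; the fit uses minimum-norm least squares
(pseudo-inverse). Under that solution the constant estimates the average
activity over all conditions and every reported contrast — constant,
target-vs-distractor within each load, and load differences pooling targets
and distractors (weights ±0.5) — is estimable, with the closed-form
two-group values verified in the tests.

Second level: the across-subject mean COPE is tested against zero by
sign-flipping whole subjects (the natural exchangeable null for mean-zero
effects; the alternative of permuting condition labels at first level is not
implemented). Each permutation records the maximum over states and time of
the signed statistic per contrast; the observed |mean| is compared with the
97.5th percentile of that maximum null. Under the symmetric null this puts
≈2.5% in each tail, i.e. a family-wise error rate of ≈5% across states and
time, which the Monte-Carlo calibration in the acceptance tests confirms
(100 null datasets, 250 permutations each). Exactly-zero statistics are
never flagged, so an all-zero input yields an empty mask.

## Spectra, modes, and networks

State spectra use Welch-style windows (default 2 s, 50% overlap) with DPSS
multitapers (time-half-bandwidth 4, 7 tapers — standard resolution choices
for a 1–40 Hz analysis at 250 Hz; all exposed in `MultitaperOptions`). Each
window's multitaper cross-spectrum contributes to state k with weight equal
to the window's mean γ_k; weighting is per window, not per sample, because a
spectral estimate needs stationarity over the window. PSD is the
cross-spectrum diagonal, coherence the normalized magnitude, clipped to
[0, 1], symmetrized, unit diagonal. A state with ~zero total weight is
reported missing (NaN) with a warning rather than dividing by zero. The
weighted estimates satisfy a mixture identity — the state-weight-weighted
sum of state spectra equals the unweighted spectrum up to estimation error —
used as a consistency test.

NNMF (multiplicative updates, best of `n_restarts` by residual) factorizes
the pooled (frequency × features) matrix jointly over all subjects, states,
region PSDs and region-pair coherences; a flag restricts the factorization
to PSD features only. Modes are reported in ascending order of peak
frequency. With the default M = 4 the last mode typically captures low-gamma
content; it is computed and reported like the others and should be
interpreted with care, as the embedding + PCA front end attenuates high
frequencies. Mode projections are inner products over frequency; group PSD
maps are averaged across subjects and z-scored across regions per (state,
mode). Coherence networks are thresholded by a two-component univariate
Gaussian mixture on the pooled connection values (raw values by default; no
variance-stabilizing transform is applied, and the mixture is fit to the
projected group coherences), keeping connections with posterior > 0.5 under
the higher-mean component; a degenerate fit falls back to a 95th-percentile
cut with a warning.

## Synthetic data

The simulator generates what the model assumes: a sticky Markov chain
(diagonal `stickiness`, uniform off-diagonal mass — the regime implied by
tens-of-ms lifetimes at 4 ms samples) over states, each a fixed region
subset carrying a sinusoid at the state's centre frequency with a fresh
random phase per visit and optional per-region lags, plus white noise
everywhere. Deterministic sinusoids (rather than AR processes) make the
spectral ground truth exact for recovery tests. The event generator
reproduces the blockwise n-back layout: 12 blocks of 20 stimuli, 4 blocks
per load, 1 s stimulus + 1.8 s inter-trial spacing, 25/23/28 targets for
0/1/2-back, block order drawn from a seeded permutation (the generator
exposes the seed rather than fixing an ordering convention); target
positions prefer slots with ≥ n preceding stimuli in the block, falling
back to unconstrained placement only when a configuration demands more
targets than such slots exist. Event-locked modulation multiplies the
transition probabilities into listed states inside (latency, window) after
each onset and renormalizes, keeping the path a valid inhomogeneous Markov
chain. Trials never straddle block boundaries; blocks are separated by a 5 s
rest (a conventional choice — the gap length does not enter any analysis).

What the simulator does **not** emulate: 1/f background spectra, measurement
leakage (so the recovery benchmark skips the orthogonalization stage, which
would otherwise remove the zero-lag coupling that *is* the signal here),
amplitude dynamics within a visit, overlapping states, subject
heterogeneity, or artifacts. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to real-recording violations of them.

## Benchmark problem sizes

The standing recovery benchmark uses 10 regions at 250 Hz for 400 s
(10⁵ samples), 3 states at 6/10/20 Hz on disjoint region triplets,
oscillation amplitude 2 against unit noise, stickiness 0.98, two restarts.
GLM calibration uses 8 subjects × 48 trials × 351 timepoints × 3 states,
100 Monte-Carlo datasets, 250 permutations. The pipeline demo runs 3–6
subjects of 100–120 s with a compressed task layout (6 blocks × 4 stimuli)
so every condition fits the short recordings; the pipeline refuses task
layouts that do not fit rather than silently truncating conditions.

## Known limitations

* K is a user choice; the package compares runs by free energy and aligned
  state similarity but implements no automatic model selection.
* The embedding + PCA front end is deliberately biased toward low
  frequencies; gamma-band structure is attenuated.
* Minimum-norm first-level estimates depend on the stated design convention;
  contrasts other than the listed estimable ones should not be read off the
  raw coefficients.
* The GMM threshold assumes a background-plus-strong two-population
  structure; heavy-tailed connection distributions may need the percentile
  fallback or a transform.
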