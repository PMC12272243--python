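# Methods

This note records the models, the numerical choices behind them, and the
scope of the synthetic data used throughout. Everything quantitative
stated here is computed by the test suite (`tests/`) or the acceptance
script (`scripts/acceptance.py`).

## Simulated data

The generator produces source-space-like parcel data in which transient,
frequency-specific networks switch on and off:

- 38 parcels, 25600 samples at 250 Hz by default.
- Each network's on/off indicator follows a symmetric two-state Markov
  chain with self-transition probability 0.95. The mean dwell time is
  geometric, 1/(1-0.95) = 20 samples (80 ms), and the stationary
  occupancy is 0.5.
- While a network is on, each member parcel carries
  `A sin(2*pi*f*t + phi)` with an independent phase `phi` per parcel per
  burst, on top of Gaussian noise with variance 0.2 that is present
  everywhere. Burst amplitudes alternate `A = 1` (low), `A = 2` (high).
- Two default networks: a 10 Hz "visual" network on six parcels
  (indices 0-5) and a 20 Hz "motor" network on four parcels (30-33).
- Finally the parcel matrix is symmetrically orthogonalised (the
  closest set of mutually uncorrelated time courses in the least-squares
  sense, preserving per-parcel scale), which removes all zero-lag
  correlations — the leakage correction applied to real
  source-reconstructed M/EEG.

Scope: this generator is a stylised testbed, not a biophysical model.
Bursts are strictly sinusoidal, noise is white and homoscedastic, and
networks are disjoint by default. Conclusions drawn from it concern the
*methods'* behaviour (recovery, calibration), not brain physiology.

### Orthogonalisation

`symmetric_orthogonalise` demeans the input, then alternates the polar
factor of the column-scaled matrix with a least-squares diagonal
rescaling until the scales converge (tolerance 1e-8 on the relative
change), and finally restores the original column norms. Because the
polar factor's columns lie in the column space of the demeaned input,
the outputs are exactly zero-mean and their sample correlations vanish
to numerical precision. Rank-deficient input raises an error naming the
offending columns (found via pivoted QR).

## Preparation

Time-delay embedding with lag half-width L = 2 augments each parcel with
lagged copies (parcel-major ordering; 38 x 5 = 190 embedded channels),
trimming L samples at each edge. PCA (eigendecomposition of the
embedded covariance) keeps 120 components; each retained component is
then z-scored. The embedded covariance encodes auto- and
cross-correlations out to +-2 samples, hence spectra and phase coupling
within the embedding window.

On the default simulation the 120 components explain about 80.7% of the
embedded variance (target `t1`; averaged over seeds).

## TDE-HMM

States are zero-mean multivariate Gaussians over the prepared data;
exactly one state is active per sample. Inference is exact Baum-Welch
EM with scaled forward-backward recursions. Numerical choices:

- Per-row max-shifted emission likelihoods before scaling.
- Covariance regularisation: `1e-6 * mean(diag) * I` added every M-step.
- Model selection: 10 seeded short runs (3 EM iterations each); the run
  with the lowest loss (negative log-likelihood per sample) continues to
  convergence (relative tolerance 1e-6, at most 40 iterations).
- Viterbi decoding in log space for the hard state path.

`hmmlearn` is used in one test as an independent oracle for the
forward-backward and Viterbi results; the implementation itself is
self-contained.

## DyNeMo

The generative model is a zero-mean Gaussian whose covariance is a
time-varying mixture, `Sigma_t = sum_j alpha_jt D_j` with
`alpha_t = softmax(theta_t)`, so modes can overlap in time. The mixing
logits follow a learned first-order autoregressive Gaussian prior
`theta_t ~ N(rho * theta_{t-1}, sigma_p^2 I)`.

Inference is stochastic variational: the posterior over logits is a
free-form mean-field Gaussian per time point, `q(theta_t) =
N(m_t, diag(s_t^2))`, optimised by Adam with analytic gradients
(reparameterised one-sample likelihood term plus closed-form AR(1) KL).
This replaces the recurrent amortised posterior of the original
formulation; with tens of thousands of time points the free-form
posterior is well determined, and it keeps the implementation in plain
numpy (no deep-learning framework is required).

Numerical choices:

- Mode covariances are Cholesky-parameterised, guaranteeing positive
  definiteness; float32 batched linear algebra.
- Warm start: 10 seeded runs of a zero-mean Gaussian mixture EM on a
  subset of samples; the best by mixture log-likelihood initialises the
  mode covariances, and the posterior means are initialised from the
  log-responsibilities on the full data.
- KL annealing: the KL weight rises linearly from 0 to 1 over the first
  half of the epochs; the reported loss is always evaluated at full KL
  weight on a strided subsample so epochs are comparable.
- Learning rates decay by 0.8 per epoch once annealing completes.
- Reported mixing coefficients are also provided trace-renormalised
  (`alpha_jt * tr(D_j) / sum_k alpha_kt tr(D_k)`), the share of total
  instantaneous variance carried by each mode.

## Frequency-resolved network descriptions

- HMM states: occupancy-weighted multitaper cross-spectra. 2 s
  non-overlapping windows, 4 Hz bandwidth (7 DPSS tapers), 1-45 Hz.
  Window weights are each state's mean posterior probability in the
  window, normalised by the state's total weight.
- DyNeMo modes: GLM spectra. A half-window-step multitaper spectrogram
  is regressed per frequency and parcel pair on the demeaned window-mean
  mode coefficients plus an intercept; a mode's spectrum is its
  coefficient plus the intercept (the spectrum at full activation).
  Because simplex coefficients make the demeaned regressors sum to
  zero, the design has one redundant direction; the minimum-norm
  pseudo-inverse solution shares it equally across modes.
- Coherence: `|P_xy| / sqrt(P_xx P_yy)` per parcel pair and frequency.
- Power maps: band-averaged PSD per parcel. HMM maps average over the
  first (lowest-spectral-centroid) component of a two-component NNMF of
  the stacked coherence spectra; DyNeMo maps average over the full
  1-45 Hz range.
- Thresholded networks keep the top 2% of edges by absolute value
  (ceil(0.02 x 703) = 15 edges for 38 parcels), ties broken
  lexicographically.

## Task-evoked analyses

Model state/mode time courses are re-aligned to the original clock by
edge-replicating the L samples trimmed by the embedding, then epoched
from -0.1 s to 1.0 s around events (inclusive start, exclusive end;
sample offsets round half away from zero) and baseline-corrected on the
pre-event 100 ms. Trial-averaged responses projected through the
state/mode spectra give a model-derived time-frequency map.

The conventional comparison uses Morlet wavelets (4 cycles, 6-30 Hz in
0.5 Hz steps, decimation 3), taking the magnitude of the transform:
full = trial-mean of single-trial amplitude; evoked = amplitude of the
trial mean; induced = full - evoked (so the three satisfy
full - evoked - induced = 0 exactly). Baseline correction is applied
per frequency, independently to each of the three.

## Permutation statistics

One-sample tests across subjects (or trials) use sign-flipping with the
maximum absolute COPE across elements as the null statistic, giving
family-wise-error control over all tested elements. P-values use the
`(1 + count) / (1 + n_perm)` estimator with the observed labelling
included as the first permutation. Calibration is verified in the test
suite: across 200 null replicates (20 subjects, 1000 permutations) the
empirical FWER lies within 0.05 +- 0.025.

## Limitations

- The free-form variational posterior for DyNeMo is not amortised; it
  cannot be applied to unseen data without re-optimising the posterior
  (the learned mode covariances and prior transfer, the per-time-point
  posterior does not).
- Spectral estimates use fixed window/bandwidth defaults chosen for
  250 Hz data and ~100 s recordings; very short recordings will fail the
  minimum-window checks rather than degrade silently.
- GLM mode spectra inherit the multitaper's 0.5 Hz frequency grid and
  4 Hz bandwidth; near-flat peaks mean the argmax frequency can jitter
  by one grid step (0.5 Hz) across simulation seeds.
- The simulation's burst lifetimes (mean 80 ms) are short relative to
  the 2 s spectral windows; the GLM-spectra regressors therefore operate
  on window-averaged coefficients, which is exactly what the mode
  spectra estimate.
- Group-level (multi-subject) pipelines enter the statistics stage as
  one averaged row per subject; session effects are not modelled.
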