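# Methods

## Stimuli

The four tone stimuli are harmonic pulse trains (amplitudes 1/h over the
first 30 harmonics) following one of the Mandarin tone F0 contours, shaped
by a fixed two-resonance "/i/-like" envelope (peaks near 300 and 2200 Hz,
implemented as IIR peak filters), gated with 10 ms cosine-squared ramps and
peak-normalized. 48 kHz, 250 ms.

The published description of the contours fixes only their endpoints and
extrema (T1 constant 129 Hz; T2 109→133; T3 min 89, max 111; T4 140→92) and
notes they derive from natural male productions. Natural tone contours have
near-zero slope at voicing onset and offset, so T2 and T4 use cosine-eased
trajectories between their endpoints and T3 two eased half-arcs meeting at
its 89 Hz minimum (at 60 % of the duration, starting from 105 Hz and ending
at 111 Hz). Easing matters for the windowed readouts: a 40 ms
autocorrelation window reports the average F0 inside it, so with a *linear*
140→92 Hz fall the final window would read ≈ 95.8 Hz, whereas the eased
contour's flat tail reads ≈ 92.8 Hz — the printed endpoint.

## Forward model

Two generators, each parameterized by latency, phase-locking knee frequency,
roll-off slope (dB/octave), and amplitude:

| source | latency | knee | slope | interpretation |
| --- | --- | --- | --- | --- |
| subcortical | 3 ms | 120 Hz | 6 dB/oct | brainstem/midbrain ensemble |
| cortical | 15 ms | 90 Hz | 18 dB/oct | thalamorecipient-layer currents |

A source's response is Σ_h (1/h)·g(h·f0(t))·sin(h·φ(t−lat)) plus a
gamma-shaped onset transient (τ = 4 ms); g is the phase-locking gain above.
Mixing weights: the scalp montage is subcortically dominated (Cz:
w_sub = 1.0, w_cort = 0.3; a T4-like temporal electrode 0.6/0.8), the
cortical-surface electrode cortically dominated (0.3/2.5), and the laminar
probe (16 contacts, 150 µm spacing) carries flat subcortical weights (0.4,
volume conduction) and cortical weights −3·(1−x²)e^(−x²/2) with
x = (depth − 1050 µm)/300 µm, i.e. a sink-like dip at the granular depth
with opposite-signed flanks — which reproduces an earliest CSD sink at the
granular contact.

Recordings are simulated at 2 kHz over a −25…275 ms epoch. Defaults are the
study conditions: 1/f noise (exponent 1) at 1.4 µV RMS, which puts the
single-trial response SNR at the Cz channel near 0.5; 60/120/180 Hz line
components (0.5/0.25/0.12 µV, random phase per trial); equal trial counts
per polarity. The cochlear-microphonic-like artifact defaults to 0 µV and is
switched on only where polarity-averaging cancellation is itself under test.
All stochastic calls draw from one seeded generator; identical seeds give
bitwise-identical datasets.

What the generator deliberately does **not** emulate: realistic head
geometry or conductivity (mixing weights are free parameters, not dipole
solutions), non-stationary arousal or adaptation effects, spike waveforms
(MUA is exercised with a separate burst-train surrogate), and
electrode-specific impedance/artifact structure. Passing tests therefore
show the *analyses* are correct and internally consistent, not that the
model reproduces any particular animal's data.

## Preprocessing and statistics

Fixed default order: line-noise regression → zero-phase third-order
Butterworth filtering → amplitude rejection → polarity averaging. Line
removal fits sine/cosine regressors at 60 Hz and two harmonics per
trial/channel (harmonics at or above Nyquist are skipped). The sEEG-style
high-pass default is 70 Hz — below the lowest stimulus F0 of 89 Hz — with no
low-pass when the sampling rate already limits the band. Rejection drops a
trial when any analyzed channel exceeds the threshold (default 75 µV),
before averaging. Polarity means are weighted equally regardless of trial
counts so sign-flipping components cancel exactly in expectation.

SNR is the RMS ratio of the 0–250 ms response window to the 25 ms
prestimulus baseline of the averaged FFR. Its significance test needed care:
the RMS of a short window is biased low relative to a long one, so a naive
response-vs-baseline comparison is anticonservative under pure noise
(observed E[t] ≈ +0.26). The implemented test therefore cuts the response
window into baseline-length segments — all compared windows share one
length — and permutes *which* window counts as baseline within each
bootstrap-resampled trial (windows of stationary noise are exchangeable).
The resulting p-values are uniform under a simulated null (KS statistic
0.05 over 200 replicates at n_boot = 1000); `n_boot < 100` is rejected as
unstable. Paired comparisons use sign-flip permutation of the Wilcoxon
signed-rank (or t) statistic, enumerated exactly for ≤ 15 pairs.

## ITPC

Each trial is convolved (FFT) with a bank of 130 analytic Morlet wavelets,
linearly spaced over 70–200 Hz. "Equal widths" is read literally as equal
*temporal* width: every wavelet shares one Gaussian envelope SD (default
40 ms), giving constant spectral bandwidth across the grid; a
constant-cycles bank is available via `n_cycles`. Coefficients are unit-
normalized, averaged across trials, and the resultant magnitude is the
ITPC. Coefficients below 1e−12 magnitude are excluded from the resultant
rather than yielding NaN unit vectors. Sampling a spectrogram along an F0
contour uses nearest-frequency lookup with edge clamping.

## Pitch tracking

Sliding-window normalized autocorrelation: 40 ms windows, 10 ms steps,
80–180 Hz search range (covering the 89–140 Hz stimulus span with margin).
F0 is the sampling rate over the best lag; pitch strength the maximum
coefficient, floored at 0; windows below strength 0.3 are unvoiced.
Parabolic peak interpolation is off by default (tracks stay on the exact
lag grid) and, when on, is clamped to ±1 lag step.

## Decoding and RSA

Pseudo-trials are disjoint random groups of k raw trials averaged together
(seeded grouping, leftovers discarded). Features are (F0, ΔF0) per window
with parabolic refinement on. One four-state left-to-right HMM with
diagonal-covariance Gaussian emissions is trained per tone (20 EM
iterations, variance floor 1 Hz²); the transition topology stays fixed
during EM because re-estimating it on short tracks can starve the final
state. Classification is argmax log-likelihood, ties to the lowest tone
index (counted and logged). Cross-validation is leave-one-pseudo-trial-out
by default, stratified k-fold as an option; no track is ever in train and
test of one fold.

RSA correlates the 12 off-diagonal confusion cells (Pearson), with a
10,000-permutation p-value (cell shuffling) — permutation rather than a
parametric test because n = 12. A perfectly diagonal confusion matrix has
no error structure; its similarity is reported NaN rather than an error.
MDS uses classical (Torgerson) scaling of the symmetrized dissimilarity
1 − (c_ij + c_ji)/2, and all configurations are Procrustes-aligned
(rotation + scale + translation) to the first.

## Scalp-versus-cortex comparison

Welch PSD/CPSD use 1024-point Hamming windows at 50 % overlap (shrunk with a
warning for shorter inputs), averaged over the four tones before the dB
normalization that pins the maximum at exactly 0 dB. Latency-by-frequency
decomposes both FFRs with a generalized Morse wavelet bank (γ = 3, β = 20;
the wavelet family follows the published analysis, the parameters are this
package's defaults) and Pearson-cross-correlates the real band signals
within ±30 ms — wide enough for every plausible cortical latency, narrow
enough to suppress cycle slipping, which is additionally flagged whenever
|lag| reaches one period at that frequency. Positive lag means the cortical
FFR lags the scalp FFR.

## Laminar CSD and MUA

CSD = −(V[d−1] − 2V[d] + V[d+1])/Δd² after Gaussian smoothing along depth
(SD 250 µm for 150 µm spacing; 125 µm for the denser-probe variant), edge
depths dropped (Vaknin padding optional). Sinks are negative by convention,
stated in the output header. The earliest sink is the first crossing of
k·SD(baseline) (k = 3; the SD gets a small floor of 1e−3 of the CSD range so
noiseless data remain analyzable) that persists ≥ 1 ms; simultaneous
crossings resolve to the strongest sink. Per-depth stimulus correlation
keeps the sign of r so polarity flips across layers stay visible; the
stimulus envelope is the default feature there, the raw waveform an option.
MUA is band-pass 300–3000 Hz, full-wave rectification, 200 Hz low-pass.

## ICA source attribution

Input is the averaged FFRs of all four tones concatenated in time across
all electrodes. PCA reduces to the smallest rank reaching the variance
threshold (default 96 %), the whitened data are unmixed with extended
Infomax (deterministic per seed), spatial weights are the pseudoinverse of
unmixing × sphering, and components are reordered by descending total PVAF
(percentage variance accounted for by the back-projection). Components
below 10 % total PVAF are excluded from labelling. Latency comes from
cross-correlation with the stimulus waveform (concatenated over tones — the
four distinct F0 trajectories break the single-tone period ambiguity);
power coherence is the |Welch cross-spectrum| with the stimulus, which is a
power measure, not phase-locking. The labelling rule is: latency < 6 ms
*and* flat intracranial weights ⇒ putative subcortical; latency ≥ 6 ms
*and* steep weights ⇒ putative cortical; anything else unclassified.
"Flat" is measured as MAD/|median| of the intracranial weights with cut
0.5 — the robust ratio, because imperfect unmixing leaves a few percent of
the large laminar cortical weights in the subcortical component's column,
which inflates an SD/mean ratio but barely moves the median statistics.
All cuts are configurable; labels are invariant to component sign flips and
reordering.

## Problem sizes

Tests and the acceptance script run entirely on synthesized data: 2 kHz
recordings, −25…275 ms epochs, a 19-channel montage, 16–100 trials per
polarity per tone depending on the stage (200 trials/tone for the decoding
benchmark), chosen as the smallest sizes at which every statistical
contract is comfortably resolved on a single CPU.

## Known limitations

* The forward model is phenomenological; mixing weights are not constrained
  by anatomy, so absolute amplitudes and scalp topographies are arbitrary.
* The HMM decoder is a generative classifier: a class with very noisy
  training tracks grows broad emission variances and can *attract* errors
  rather than suffer them, so per-class accuracy orderings under asymmetric
  noise depend on how the degradation manifests in the tracks.
* Latency estimates based on cross-correlation with a periodic stimulus are
  only unambiguous when several distinct F0 trajectories are pooled.
* Zero-phase filtering spreads onset energy a few milliseconds backward in
  time; earliest-sink latencies on filtered data inherit that smear.
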