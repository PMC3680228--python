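# Methods

## Problem and model

A single bipolar surface-EMG channel over the flexor digitorum
superficialis integrates the activity of several muscle compartments,
one per finger.  Volume conduction attenuates bioelectric potentials
with distance — more strongly transverse to the fibre direction — so the
motor-unit action potentials (MUAPs) of each compartment arrive at a
fixed electrode with a characteristic amplitude.  During a weak
isometric flexion MUAPs are sparse, so the recording is approximately a
sum of amplitude-stamped singular events plus background activity:

    x(t) = Σ_m g_m Σ_j h_m(t − t_{mj}) + n(t)

with `g_m` the volume-conduction gain of muscle `m`, `h_m` its unit
MUAP waveform, `t_{mj}` a renewal point process, and `n(t)`
non-stationary noise.  Which finger is flexing is then encoded not in
total signal power but in *which amplitude level* the singularity
density concentrates on.  The pipeline estimates that encoding
directly:

1. **Denoising.**  Zero-phase Butterworth bandpass (4th order per pass,
   10–450 Hz), then short-time spectral subtraction of a noise
   magnitude-spectrum template averaged over ≥ 20 Hann windows of a
   background (rest) recording of the same subject/session.  Per-frame
   magnitudes become `max(|X| − α·template, 0)` (α = 1 by default); the
   noisy phase is reused and the signal rebuilt by overlap-add.  The
   template is re-estimated per session because the background spectrum
   is not stable across sessions — that re-estimation is what makes the
   filter adaptive.  Amplitudes are standardized by one session-level
   RMS constant (the RMS of the class-1 recordings), never per
   recording: a per-recording RMS would erase the between-class
   amplitude differences the method depends on.
2. **Singularity detection.**  Undecimated (à trous) wavelet transform
   of the bior3.3 biorthogonal pair, 4 dyadic scales.  Local maxima of
   the coefficient modulus are strict interior peaks
   (`|W|(n−1) < |W|(n) > |W|(n+1)`); endpoints and plateaus never
   qualify.  A maximum is kept only if it can be tracked from the
   finest to the coarsest scale (greedy nearest-position matching,
   tolerance 2^s samples at scale s, largest-magnitude-first; distance
   ties resolved toward the larger coarse magnitude; every maximum
   belongs to at most one chain; chains touching the boundary region
   are dropped).  Maxima that do not persist are discarded as random
   transients.  The finest-scale magnitudes of the surviving chains
   are the event amplitudes.
3. **Feature assembly.**  The persistent-maxima stream of each flexion
   is cut into 300 ms windows (307 samples at 1024 Hz; 25 windows per
   7.5 s flexion; a 200 ms alternative is available).  Magnitudes are
   grouped into k = 4 clusters — one per candidate muscle — and each
   window yields 8 features: the four cluster centroids (ascending) and
   the four occupancy counts (densities).
4. **Classification.**  Linear twin support vector machine (TSVM),
   one-vs-rest.  For each class two nonparallel hyperplanes are fitted
   by a pair of small QPs (plane 1 close to the class, pushed unit
   distance from the rest; plane 2 mirrored); a point takes the class
   whose own plane is nearest in normalized distance.  Features are
   z-standardized with training-split statistics.
5. **Evaluation.**  Repeated stratified random sub-sampling — 100
   training and 30 test windows, 10 repetitions — reporting per-class
   accuracy (one-vs-rest recall), sensitivity and specificity as
   mean ± SD percent.  Stratified 10-fold cross-validation is provided
   as an alternative mode.

## Design choices where the design was open

**Analysis side of the biorthogonal pair.**  The à trous cascade must
smooth with the *spline* (reconstruction) side of bior3.3.  Its dual
(decomposition) lowpass leaks ≈ 30% of the dilated detail response
energy above 0.2 cycles/sample, so coarse scales carry broadband ripple
whose spurious modulus maxima persist across scales and neutralize the
transient-rejection step (measured pure-noise chain rate ≈ 0.86 of the
finest-scale maxima rate, vs ≈ 0.25 with the spline side, whose leakage
is 0.9%).  This is the standard choice in wavelet singularity
detection, where the smoothing kernel is the smooth spline and the
wavelet acts as its derivative.  `analysis_side="dual"` restores the
literal decomposition filters.

**Modulus vs signed maxima.**  The peak test runs on |W| by default:
MUAPs are biphasic, so both polarities carry events and a signed-only
test would drop about half of them.  `signed_maxima` restores the
signed reading.

**Exact 1-D clustering.**  "Cluster analysis" on scalar magnitudes is
solved exactly: 1-D k-means optima are contiguous partitions of the
sorted values, so a dynamic program (O(k·n²)) finds the global
within-cluster-SSE optimum deterministically.  This removes both seed
sensitivity and local-minimum artifacts of Lloyd iterations; ties take
the first optimal split, and a window whose magnitudes have fewer than
k distinct values is flagged degenerate.

**Cluster correspondence across windows** (`clustering.mode`).  With
`"window"`, every 300 ms window is clustered independently and cluster r
is matched across windows by ascending centroid rank.  That rank is not
stable: at 20 pulses/s the active muscle fires about 6 times per
window, so windows in which the strongest-amplitude source happens not
to fire promote a weaker magnitude level into the top slot, and the
rank-averaged features blur.  On the synthetic study this caps linear
separability near 87% regardless of classifier and even without noise.
The default `"flexion"` mode therefore estimates the k magnitude levels
once from all maxima of the flexion (same exact clustering) and counts
each window's maxima against those shared levels (nearest-centroid
assignment, boundaries at centroid midpoints).  Every window yields a
row; empty windows count zero everywhere.  In `"window"` mode, windows
with fewer than k maxima are excluded rather than padded, since
fabricated empty clusters would bias the density means.

**Classifier input granularity.**  Windows are the classification unit
(one feature row per 300 ms window), matching both the 100/30 protocol
arithmetic and real-time operation, where 300 ms is the permissible
decision delay.  Rank-wise flexion averages (`flexion_features`) are
also provided for session-level summaries.

**TSVM solver.**  Each dual is a box-constrained convex QP over the
opposite class's multipliers.  It is solved by a primal active-set
method: Newton step on the free set, truncated at the first blocking
bound; at a free-subspace optimum the most violated bound multiplier is
released.  The method is finite and exact on its final active set,
which matters because the normal-equation matrices `HᵀH + ε·I`
(Tikhonov ε = 10⁻⁶) can be poorly conditioned when a class has few
points relative to the feature dimension.  Penalties default to
c₁ = c₂ = 1.  Multiclass assembly is one-vs-rest with minimum
normalized distance to the own-class plane, ties to the lower class
index.

## Synthetic data: what it emulates and what it does not

`generate_dataset` emulates one recording session: four classes ×
12 flexions × 7.5 s at 1024 Hz, plus a 10 s rest recording for the
noise template.  Four sources share a 10 ms biphasic
(Gaussian-derivative) MUAP template with amplitude gains in geometric
progression (ratio 1.5 from 1.0) — the volume-conduction ladder.  The
flexed finger's source fires at 20 pulses/s; the others keep a 5
pulses/s background (the physiological floor of motor-unit discharge);
inter-pulse intervals are Gaussian-jittered with CV 0.15.  Noise is
white Gaussian shaped to the 20–450 Hz amplifier band and scaled to RMS
0.1 relative to the weakest source's unit peak; an optional slow
sinusoidal drift exercises the adaptive filter.  Every trial draws from
an independent counter-derived substream, so datasets are reproducible
sample-for-sample.

Real sEMG differs in ways the generator does not model: per-muscle
template shape differences and motor-unit pools with heterogeneous
amplitudes within a muscle, recruitment/derecruitment dynamics, firing
rate modulation, MUAP superposition at higher forces, electrode
movement, powerline interference and ECG contamination.  Passing the
synthetic study therefore shows that the chain
denoise → persistence → magnitude-density → TSVM recovers amplitude-
coded source identity under the model's assumptions (sparse events,
stable per-source amplitude, stationary-in-session noise); it does not
certify the headline recognition rates on human recordings.

## Numerical notes

- Window arithmetic: 300 ms at 1024 Hz → ⌊0.3·1024⌋ = 307 samples,
  ⌊7680/307⌋ = 25 windows per flexion; windows are half-open
  `[start, start+L)`, a maximum on the boundary belongs to the later
  window, the trailing partial window is dropped.
- STFT: periodic Hann, 256 samples, 50% overlap — exact overlap-add
  reconstruction, so a zero template is the identity (RMS error
  < 10⁻¹⁵ in practice).
- The noise template requires ≥ 20 averaged windows and rejects shorter
  background recordings with the required length in the message.
- Degenerate inputs: all-zero recordings are rejected at RMS
  normalization; decomposition of a too-short signal reports the
  maximum feasible depth; an all-equal magnitude window is flagged.
- Boundary margin for chains: half the dilated filter support at the
  coarsest scale (28 samples for 8-tap filters at 4 scales).
- All randomness descends from one master seed (per-trial substreams
  via `SeedSequence(seed, spawn_key=(counter,))`, kept below 2³¹).

## Evaluation sizes

The default study (48 flexions of 7.5 s) yields 1200 window rows; the
100/30 protocol with 10 repetitions tests 300 windows per run.  Signal-
level diagnostics (noise-chain rate, subtraction strength) use 8 s
segments at 1024 Hz.  The full pipeline runs in seconds on one CPU.

## Known limitations

- The number of scales (4), the linking tolerance (2^s) and the cluster
  count (k = 4, tied to the number of actions) are fixed design
  parameters; no data-driven selection is attempted.
- Persistence filtering is scale-invariant: arbitrarily small noise
  still produces chains (about a quarter of its finest-scale maxima),
  so the magnitude clusters always contain a noise-floor group.
- The session RMS constant presumes class-1 recordings exist in every
  session.
- Only the linear TSVM kernel is implemented; no probability
  calibration, no online training.
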