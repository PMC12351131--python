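# Methods

## Signal model and conditioning

Input is a single-lead ECG sampled trace. The working rate is 256 Hz;
records at other rates are polyphase-resampled (anti-aliased, R-peak
indices rescaled and rounded to the nearest sample). Conditioning is a
zero-phase Butterworth bandpass, default corners 0.5–40 Hz at order 4,
applied forward–backward with `scipy.signal.sosfiltfilt`. The band is an
implementation choice: it rejects baseline wander (≈ 0.15–0.3 Hz,
≥ 20 dB down after the squared response of the forward–backward pass),
60 Hz mains and everything above (EMG beyond 40 Hz, electro-surgical
bands) while keeping QRS energy (≈ 5–25 Hz) essentially untouched.
Harmonics of 60 Hz are handled by the low-pass corner; no notch filters.
Amplitude is normalized to unit maximum absolute value, and
`floor(0.01·n)` samples are trimmed from each end of the record
(acquisition edge artifacts); annotations falling inside trimmed regions
are dropped, the rest shifted. Trimming uses sample-count floor so it is
deterministic.

## QRS detection

The Pan–Tompkins detector with its classic constants: detector-internal
bandpass 5–15 Hz, derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds (signal/noise running estimates
with 0.125/0.875 updates, decision threshold NPKI + 0.25·(SPKI−NPKI)),
search-back at 1.66× the running RR average against the lower threshold,
a 200 ms refractory period, and T-wave rejection by slope comparison for
candidates within 360 ms of the previous beat. Reported positions are
refined to the maximum of the detector's bandpassed signal within
±100 ms of the integrator peak, so indices are R-wave aligned for
segmentation. The first 2 s initialize the thresholds and any detection
there is discarded. A flat record yields an empty detection; a record
shorter than 2 s is an error. When a record carries annotated R-peaks
the default policy (`annotations_first`) uses them verbatim.

## Statistical cycles

Each R-peak PR spawns the half-open, 0-based window
`[PR − round(fs·λ), PR − round(fs·λ) + L)` with `L = round(fs·(λ+θ))`,
defaults λ = 0.4 s, θ = 0.6 s, λ + θ ≤ 1 enforced. The cycle length is
fixed first and the post-window is L minus the pre-window, so the matrix
is uniform even when fs·λ is fractional (256·0.4 = 102.4 → R offset 102;
rounding is half-away-from-zero). Windows that would cross a record edge
are dropped and counted. When RR < 1 s consecutive windows overlap; they
are retained, not deduplicated, because the window length is fixed
irrespective of heart rate.

## Moment features

For a cycle x₁…x_N with median η:

- σ_η² = (1/N) Σ (xᵢ − η)²  — median variance
- σ_η = √σ_η²               — median standard deviation
- ψ_η = (1/N) Σ (xᵢ − η)³ / σ_η³ — median skewness
- κ_η = (1/N) Σ (xᵢ − η)⁴ / σ_η⁴ — median kurtosis

and the classical mean-centered quadruple with the same population (1/N)
conventions. The third and fourth standardized moments are normalized by
1/N by default so that both families share a convention and κ of a large
normal sample is ≈ 3; without that factor the statistics grow linearly
with N and are comparable only at fixed cycle length. The literal
un-normalized forms remain available via `raw=True`. Useful identities:
the mean minimizes the sum of squared deviations, so σ_η² ≥ σ² always,
with equality iff mean = median; with the 1/N convention κ ≥ 1
(power-mean inequality, minimum attained by a symmetric two-point mass);
mean- and median-centered features of the same cycle differ only through
the per-cycle gap Δ = x̄ − η. Zero-dispersion cycles have undefined
standardized moments; they are excluded with a logged count rather than
given sentinel values, so they cannot poison training.

## Classifier and evaluation

One hidden layer (presets 5, 10, 100 neurons), two output classes,
log-loss. Default training is ReLU + Adam, learning rate 0.01, at most
1000 epochs, tolerance 1e-4 (scikit-learn `MLPClassifier`); a
sigmoid + SGD configuration is available. The default input is the
3-vector (variance, skewness, kurtosis); `n_inputs=4` adds the center
statistic. Features are standardized to zero mean / unit variance using
training-fold statistics only — necessary for stable MLP training and
free of test-set leakage.

Evaluation is subject-grouped throughout: the 70/30 holdout stratifies
subjects by class (and sex when provided) with `floor(n·fraction)`
training subjects per stratum; grouped k-fold shuffles subjects within
class by seed and deals them round-robin across folds. A subject never
straddles a split, which is the leakage-free way to estimate
generalization to unseen patients; with fewer subjects than folds the
effective fold count drops to the subject count (a fold needs at least
one whole held-out subject). Each cycle is one classification instance;
a per-subject majority vote can be layered on the per-cycle report but
is kept separate. Sensitivity = TP/(TP+FN) with epilepsy positive,
specificity = TN/(TN+FP); a metric whose denominator is empty is
reported as NaN, never 0. Aggregates are mean ± standard deviation
across folds, formatted to two decimals. Two runs with the same seed,
data and config produce identical reports, and a precomputed split plan
lets both feature families be scored on identical folds for a paired
comparison.

## Synthetic cohort

Each beat is a sum of five Gaussian waves; defaults (amplitude a.u.,
latency s, width s): P(0.12, −0.20, 0.020), Q(−0.10, −0.025, 0.010),
R(1.0, 0, 0.010), S(−0.15, 0.025, 0.010), T(0.30, 0.25, 0.035). Beats
are placed on the integer sample grid at intervals drawn per-beat from a
normal heart-rate law, extending ~1.5 s past both record edges so edge
cycles see the same neighbour tails as interior ones; ground-truth
R-peak indices are exact by construction. The wave widths are narrower
than textbook sketches on purpose: they keep the true baseline in the
majority within a 1-s window at 70–95 bpm, which is precisely the regime
in which the cycle median is an outlier-robust center. With wider waves
the median lands on wave slopes, is noisier than the mean, and the
median-centered features lose their advantage — the method's own
premise.

Class presets: healthy = 70 ± 3 bpm, 2% per-cycle amplitude jitter, no
deformations; epilepsy = 95 ± 8 bpm, 10% jitter, and with probability
0.15 a transient deformation (T-wave amplitude ×1.4–2.4 and widened,
S-wave deepened ×1.5–3.5), producing the elevated cross-cycle variance,
skewness and kurtosis that characterize the epileptic class. Seven noise
sources with per-source amplitudes: 60 Hz sinusoid, 0.15–0.3 Hz
sinusoidal wander, 20–120 Hz filtered white noise (EMG), smooth
unipolar baseline bumps ~0.2–0.4 s wide (electrode motion / impedance
steps; default amplitude 0.10 — these displace a cycle's mean but
barely its median, the main artifact against which the median features
are robust), brief saturations (contact loss), ≥ 100 Hz band noise
(electro-surgical) and white instrumentation noise. Both class presets
share the same noise floor, so noise never encodes the label. All
randomness flows from one seed; per-subject seeds and mild per-subject
morphology perturbations derive deterministically from the master seed.

The default cohort is 10 + 10 subjects × 100 cycles ≈ 1,000 + 1,000
cycles — the scale of the study design the package follows. These sizes
are also what the test suite and `scripts/acceptance.py` use.

What the generator does *not* emulate: real P/QRS/T shape variation
beyond Gaussian bumps, arrhythmias and ectopy, respiration-modulated
morphology, sensor-specific transfer functions, or the specific
morphology of clinical recordings. Passing the end-to-end tests
therefore shows the pipeline is correct and that the median-feature
advantage materializes under controlled artifact contamination — not
that the same accuracy would be obtained on clinical data.

## Numerical choices and degenerate inputs

- Rounding of window geometry: half-away-from-zero, fixed before the
  post-window is derived.
- WFDB-style output quantizes to a 12-bit ADC over a 10-unit span by
  default (round-trip error ≤ half a quantization step); CSV output is
  full precision (17 significant digits).
- Filters are applied forward–backward (zero phase); the effective
  magnitude response is the square of the design response.
- All-zero signals: normalization and QRS detection treat them as
  degenerate (error and empty detection respectively).
- Records whose every peak window crosses an edge fail segmentation
  loudly rather than returning an empty matrix.

## Known limitations

- The WFDB support is a minimal subset (formats 16 and 212 read, 16
  written; plain-text R-peak sidecars instead of binary annotation
  files).
- The holdout/CV combination found in practice (a fixed patient split
  *plus* k-fold) is ambiguous; both modes are provided (`mode="holdout"`,
  `mode="cv"`) without claiming either is canonical.
- Per-cycle features ignore inter-beat (HRV) information by design; the
  method reads within-cycle morphology only.
- The acceptance study is synthetic; clinical validation requires the
  corresponding public databases and is out of scope here.
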