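# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates.  Notation: frames are indexed
`(row, col)`, 0-based, row increasing downward; "vertical" is always the
row coordinate.  Temperatures are degrees Celsius internally; the
radiometric calibration (16-bit counts × scale + offset) lives only at
the I/O boundary, because both signal paths use temperature
*fluctuations*, never absolute radiometry.

## Heart-rate branch

**Model.** Cardiac ejection accelerates the head mass; at rest the
dominant visible component is a vertical oscillation of the whole head
at the cardiac fundamental, far below one pixel at typical camera
distances.  The branch treats the head as a rigid vertical translator
and reads the oscillation frequency, not its amplitude.

**Preprocessing.** Every frame is segmented by multilevel Otsu
thresholding (between-class variance maximized over a 256-bin histogram
of the frame's value range; 2 classes by default, configurable to 4) —
easy in thermograms because skin is warmer than the room.  The raw
mask keeps its largest connected component and holes are filled; bare
thresholding leaves speckles that corrupt corner scoring.  In-mask gray
levels are then linearly stretched so the 1st/99th percentiles map to
0/1 and out-of-mask pixels are set to 0.  Segmentation and stretch are
recomputed per frame, which makes the pipeline exactly invariant to a
global temperature offset.

**Features and tracking.** Shi-Tomasi cornerness is the smaller
eigenvalue of the 2×2 Sobel structure tensor averaged over a 5×5
window, computed in closed form.  Up to 100 corners are selected
best-first inside the user-supplied lower-face rectangle (mouth
rectangle excluded; quality floor 0.01 × ROI maximum; 5 px minimum
spacing).  The ROI is a user input by design — the study protocol this
implements selected it manually.  Tracking is frame-to-frame pyramidal
Lucas-Kanade with a pure-translation model: 3 levels, 21 px patches,
bilinear sampling, normal equations from the previous frame's patch
gradients, iterated to a 0.01 px update (max 30 iterations).  Points
are invalidated permanently when their patch leaves the frame, the
normal matrix degenerates, or the mean absolute residual exceeds 0.25
(on unit-stretched frames); there is no re-detection, so every
surviving trajectory covers the same span.  On rigid-translation
scenes the tracker recovers commanded sub-pixel sinusoids with < 0.05
px RMS error for amplitudes of 0.1–2 px.

**Erratic-point pruning.** Per point, the maximum inter-frame step
magnitude is compared with the 95th percentile of all step magnitudes
pooled over points and frames; points strictly above it are dropped.
The pooled definition keeps the rule well defined for heterogeneous
track lengths.  A floor of 10 surviving points (best-ranked by
steadiness) protects the PCA from over-pruning: with continuous noise
distributions, the per-track maximum of hundreds of steps generically
exceeds any fixed pooled percentile, so on long recordings the floor is
often what determines the surviving set.

**Windowed decomposition and readout.** Per 256-sample window (5.12 s
at 50 fps; stride 50 samples = 1 s; timestamps at the window center),
each vertical trajectory is mean-removed and filtered by a zero-phase
(forward-backward) second-order Butterworth band-pass, 0.65–5 Hz.  The
wide band keeps cardiac harmonics for the periodicity score; the
readout band is the fundamental only (0.65–2 Hz, i.e. 39–120 bpm).
Zero-phase filtering is used because the PCA compares channels: IIR
phase distortion would mix them inconsistently.  Its side effect is a
squared magnitude response (gain 0.5 at the nominal 3 dB cutoffs),
which the tests assert explicitly.  The ceil(0.15·n) columns with the
largest L2 norms are excluded (gross motions dominate variance), PCA is
computed per window from the SVD of the centered matrix, and the first
six components are scored.

**Periodicity score.** Each component's amplitude spectrum is computed
with a Hann taper, zero-padding to 4096 samples, and FFT; the dominant
frequency is the in-band argmax refined by 3-point parabolic
interpolation (ties toward the lower frequency).  The score is the
fraction of total power within ±0.05 Hz of the dominant frequency plus
±0.05 Hz of its first harmonic.  A geometric consequence worth noting:
at a 256-sample window the Hann mainlobe (±2/T ≈ ±0.39 Hz) is wider
than the ±0.05 Hz integration band, so even a noiseless sinusoid scores
≈ 0.32 — the score saturates toward 1 only for windows long enough that
the mainlobe fits inside the band (asserted at 4096 samples in the
tests).  What matters operationally is separation, not the absolute
value: measured on synthetic scenes, the best-of-six score of pure
band-limited tracking noise stays below ≈ 0.18 while true cardiac
windows score ≥ 0.32.  The estimate gate `min_periodicity = 0.25` sits
at the midpoint; windows whose best component scores below it yield no
estimate rather than a confident wrong one (a zero-amplitude scene
therefore returns an empty series).  Estimates outside 39–120 bpm are
likewise dropped.

## Respiratory-rate branch

**Model.** Nasal airflow modulates the temperature of the nostril
margin: cooling during inspiration, warming during expiration.  The
respiratory waveform is the spatial mean of a measurement rectangle
(ROM), the centered sub-rectangle with half the area of the tracked
nose ROI (aspect preserved) — averaging trades spatial resolution for
SNR.  Tracking is deliberately "rough": integer-pixel normalized
cross-correlation of the first-frame template within ±20 px of the
previous position; a correlation peak below 0.3 (or a zero-variance
template) raises a typed tracking-loss error carrying the frame index.

**Interval estimation.** The filtered waveform (zero-phase Butterworth,
0.1–0.85 Hz, order 2) is scanned at 1 s strides.  At each center, for
every candidate lag m in [⌈fs/0.85⌉, ⌊fs/0.1⌋] samples (59–500 at
50 fps), three estimators are evaluated over the adaptive window
spanning [−m, m] around the center: the adaptive-window
autocorrelation, the reciprocal average magnitude difference function
(ε = 1e−12 guard; the reciprocal makes maxima mark the interval, and
matches the estimator family this fusion scheme was designed around),
and maximum amplitude pairs.  Each profile is shifted by its minimum
and normalized to a probability mass over lags (all-equal profiles
become uniform — this conversion is this package's choice; the fusion
literature leaves it open), and the three are fused elementwise as a
naive-Bayes product.  A degenerate all-zero product falls back to the
autocorrelation posterior with a warning.

**Subharmonic readout.** For a perfectly stationary periodic waveform,
every integer multiple of the true interval explains the window equally
well, so the fused posterior carries near-equal peaks at m, 2m, 3m and
a plain argmax picks among them essentially at random (observed as
rate-halving/thirding on constant-rate synthetic breathing; real
breathing is variable enough that long lags decohere).  All those peaks
are evidence for the shortest of them, so the pipeline reads the
*smallest local posterior maximum within 0.5× the global maximum* — a
threshold rule standard in lag-domain period estimation.  On a unimodal
posterior this is exactly the argmax; the fusion function itself keeps
the pure argmax contract (ties toward the smaller lag).  The rate is
RR = 60·fs/m̂ with no sub-sample lag interpolation: near 15 breaths/min
at 50 fps the lag grid is ≤ 0.08 breaths/min wide, finer than any error
this method is expected to deliver.  Estimates outside 6–51 breaths/min
are dropped.

## Synthetic scenes

The generator renders the study conditions: a warm ellipse (34 °C skin,
smoothed frozen speckle of 0.8 K SD for trackable texture) on a 22.3 °C
background, 50 fps, i.i.d. Gaussian sensor noise of 0.025 K (the
camera-class NETD), whole-head vertical sinusoid at the cardiac
frequency rendered by bilinear resampling (default 0.3 px — a test
choice placed firmly sub-pixel; no measured pixel amplitude exists),
and an additive nostril oscillation (default 0.5 K peak,
cold-on-inspiration) that is sinusoidal or asymmetric
(fast-inspiration, via the phase-warped sine sin(φ − 0.5·sin φ)).
Optional linear vertical drift emulates posture change.  Everything is
deterministic given the seed; truth series are constant rates sampled
at 1 Hz.

What the scenes do *not* emulate — facial deformation (speech,
swallowing, expression), rotation, breathing-driven head motion,
illumination/emissivity structure, occlusions, multi-person scenes —
bounds what green tests mean: they certify the signal path (geometry,
filtering, decomposition, interval fusion) at realistic amplitude and
noise, not performance on real faces.

## Numerical and design choices

* Otsu histograms: 256 uniform bins over [min, max]; thresholds are
  reported as bin centers, so any threshold within an empty-bin run is
  equivalent — oracle tests therefore compare attained between-class
  variance, not raw threshold values.
* Percentiles (contrast stretch, pruning, ε₉₀): linear interpolation
  between order statistics.
* PCA sign convention: each component's largest-magnitude loading is
  positive; rank-deficient windows return fewer components with a flag.
* L2-exclusion ties drop the higher column index; component-score ties
  keep the lower (higher-variance) index; spectral argmax ties take the
  lower frequency; fused-lag ties take the smaller lag.
* Tracker internals run in float32 (images) with float64 solver
  accumulations; sub-pixel sampling is clamped bilinear interpolation.
* Bland-Altman limits use 1.96 × sample SD (n−1 denominator), pooled
  over aligned instantaneous pairs; reference series are linearly
  interpolated onto estimate timestamps inside the overlap.
* Table-level statistics are provided both per-pair (RMSE, ε̄, ε₉₀ on
  aligned windows) and per-subject (mean-rate relative error, CAND),
  because validation studies report both.
* Degenerate inputs raise typed errors (configuration, format,
  degenerate-input, segmentation, feature-scarcity, tracking-failure/
  loss, alignment, domain); the pipelines wrap stage failures in a
  `PipelineError` naming the stage.

## Problem sizes

Recovery checks run on 128×128 px scenes, 60 s at 50 fps for the
acceptance script and acceptance tests (the study geometry scaled to a
head-sized crop), and on 48–96 px scenes of 2–40 s for module tests —
sizes chosen so the whole suite exercises every stage end-to-end while
staying comfortably interactive on one CPU.

## Known limitations

* The HR branch assumes a single rigid head; it has no motion-artifact
  detector and will gate out (rather than flag) windows dominated by
  non-periodic motion.
* ROIs are manual by design; no face or nose detection is included.
* The RR readout reports one rate per window, not breath-by-breath
  timestamps; the HR readout is likewise one frequency per window (no
  beat-to-beat variability).
* Per-frame contrast stretching makes mask-boundary pixels flicker as
  the head moves; corners seeded very close to the segmentation
  boundary on small scenes can be invalidated by the residual check.
  At the default geometry enough interior corners survive, and the
  validity/pruning machinery exists precisely to absorb this.
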