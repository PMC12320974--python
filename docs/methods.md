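# Methods

This note records the models, algorithmic choices and parameter defaults of
the `flyheart` package, and what each choice does and does not claim.

## 1. Beat-interval model (`flyheart.synth`)

Intervals are drawn i.i.d. from a log-normal law, optionally mixed with
"pause" beats:

- Base law: `I ~ LogNormal(mu, sigma)` with `sigma^2 = ln(1 + cv^2)` and
  `mu = ln(m) − sigma^2 / 2`, so the mean is exactly `m = mean_period` and
  the coefficient of variation exactly `cv = period_cv`.
- Pause mixture: with probability `pause_prob` an interval is multiplied by
  `pause_factor` (default 2.0). Mixture moments are closed form:
  `E[I] = m (1 + p (f − 1))` and `E[I^2] = m^2 (1 + cv^2)(1 − p + p f^2)`,
  which the tests use as oracles.
- Event times are laid down from a uniform random phase offset; a recording
  shorter than one mean period, or containing fewer than two events, raises
  `TooFewBeatsError`.

`cv_for_arrhythmicity_index` inverts the AI definition (SD/median of the
law) to find the `cv` that hits a target AI exactly in law, using the closed
form `cv^2 = (sqrt(1 + 4 AI^2) − 1) / 2` without pauses and Brent's method
on the mixture otherwise. This is calibration *in law*: a finite 30-s window
(~60 intervals) still shows sampling scatter around the target.

## 2. Wall motion and rendering

The tube wall positions follow a diastolic diameter `DD` with raised-cosine
contraction pulses centered on each event: compact support of width
`pulse_width` (default 0.2 s), exact systolic diameter at pulse center, zero
motion outside the pulse. Overlapping pulses are a modelling error and raise
`OverlappingPulsesError` naming the offending pair. Optional linear drift
models slow tube movement.

Kymographs render the two walls as dark Gaussian bands on a bright
background: band profile `exp(−(x − wall)^2 / (2 s^2))` with
`s = wall_thickness / (2 sqrt(2 ln 2))`, i.e. `wall_thickness` is the
full width at half maximum. Additive white Gaussian noise with SD
`noise_sd` is applied; the default contrast of 0.8 makes
`noise_sd = 0.08` a contrast-to-noise ratio of 10. `render_stack` renders a
full movie of a horizontal tube such that the vertical center scan line
reproduces `render_kymograph` bit for bit — the tests assert exact equality.

Defaults: 30 s at 100 frames/s, 80 spatial pixels at 1 µm/px, `DD` 50 px,
systolic diameter 30 px (FS 40%), mean period 0.5 s (HR 120 BPM).

## 3. Kymograph construction (`flyheart.kymo`)

A scan line of length `L` pixels is sampled at unit steps, giving
`floor(L) + 1` samples, with bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1). Lines leaving the image raise
`GeometryError`. `suggest_line` picks a line automatically from the temporal
variance map: the line passes through the variance-weighted centroid along
the dominant eigenvector of the gradient structure tensor of the smoothed
variance map. The structure tensor is used instead of the raw second-moment
principal axis because the variance map of a beating tube is two parallel
stripes: its intensity principal axis runs *along* the walls, while the
gradient tensor's dominant direction crosses them, which is the direction a
useful M-mode line needs. A flat movie raises `NoMotionError`.

## 4. Beat detection (`flyheart.beats`)

The per-frame trace is the mean of a small window (default 5 rows) of
kymograph rows around a chosen profile row, smoothed by a moving average
that shrinks at the edges rather than padding.

**Profile-row choice.** The default `systolic` strategy finds, in the
temporal-minimum profile, the widest bright gap between dark wall bands
(the lumen) and takes the adjacent wall-edge rows, picking the one with
higher temporal variance. The naive alternative — the global
variance-maximum row — sits near the diastolic dwell position of the wall,
where the trace plateaus between beats and can dip twice per contraction;
rows at the systolic excursion see one sharp dip per beat, which is what
makes ±1-frame timing possible. The `variance` strategy is retained as an
option.

**Peak detection.** Contractions are minima of the smoothed trace found by
`scipy.signal.find_peaks` with prominence threshold
`max(k · sigma_noise, 1e-6 · range)` where
`sigma_noise = 1.4826 · MAD(diff(trace)) / sqrt(2)` (robust to the beat
signal itself), `k = 4` by default, and a refractory distance of 0.15 s.
Detections within `max(window, 2)` frames of either trace edge are
discarded: pulses truncated by the recording boundary combine with the
shrinking smoothing window to bias the apparent minimum by more than a
frame, so edge events are treated as unmeasurable rather than mistimed.

**Diameters.** Ten systolic columns (at detected events) and ten diastolic
columns (at beat midpoints) are measured; in each column the two most
prominent spatial minima are wall centers, refined to sub-pixel by parabolic
interpolation. Columns with fewer than two walls are logged and skipped.

## 5. Endpoints (`flyheart.metrics`)

`HR = 60 / mean(I)`; `AI = SD(I) / median(I)` with the sample SD
(`ddof = 1`); `FS = (DD − SD)/DD × 100` with `DD`, `SD` the means of the
ten-column measurements. AI is exactly invariant under time rescaling and
FS under pixel-size changes — both are asserted as properties. A negative
FS is returned but logged as a warning (it indicates mis-detected walls).

## 6. Poincaré ellipses (`flyheart.poincare`)

Lagged pairs `(I_n, I_{n+1})` are fit with the sample mean and covariance
(`ddof = 1`). The 0.99 confidence ellipse is the Mahalanobis ball of squared
radius `q = chi2.ppf(0.99, df=2) = −2 ln(0.01) ≈ 9.2103`; its area is
`pi · q · sqrt(det(cov))`, reported in ms² by default (seconds² × 10⁶).
Identity covariance gives area ≈ 28.94. Nearly singular covariance
(constant or collinear intervals) yields a `degenerate` flag and zero area
instead of an exception; percent-change comparisons against a degenerate
baseline raise `DegenerateDataError` advising absolute areas.

The ellipse is a normal-theory construction applied to interval data that
are log-normal and autocorrelation-free by model; Monte Carlo tests confirm
~99% coverage of fresh same-law points at n = 500 pairs.

## 7. Statistics (`flyheart.stats`)

**Wilcoxon signed-rank (paired, two-sided).** Zeros dropped
(`zero_method="wilcox"`, `"pratt"` available), midranks on `|d|`. For up to
16 nonzero pairs the p-value is computed by exact tie-aware enumeration of
all 2^n sign assignments (vectorized via a cached sign matrix), counting
outcomes at least as extreme under the null symmetric about `sum(ranks)/2`.
Above 16 pairs a normal approximation with continuity correction toward the
mean and the tie variance term `sum(t^3 − t)/2` is used. The cutoff of 16
was chosen because at the study's n = 15 the approximation's true size
(0.041 at α = 0.05) is visibly conservative, while the exact test's size is
0.048; enumeration at n = 16 costs ~65k sign vectors, i.e. milliseconds.

**Kruskal–Wallis.** Midranks, tie correction `1 − sum(t^3 − t)/(N^3 − N)`,
chi-square reference with k − 1 degrees of freedom.

**Study runner.** `run_study_comparisons` performs per-strain paired
Wilcoxon tests on HR/AI/FS, Kruskal–Wallis across strains within each
condition, and optional Holm-adjusted pairwise comparisons. The contractile
dysfunction flag requires p < α *and* the deleterious direction (HR down,
AI up, FS down). Animals missing one condition are excluded from pairing
and logged. Significance stars: `*` < 0.05, `**` < 0.01, `***` < 0.001,
`****` < 0.0001.

## 8. Cohort generator

`CohortDesign` emulates the study: per-cell `GroupEffect` (BTP heart rate
120 BPM, BTP AI 0.08, pacing HR drop `d_hr`, post-pacing target AI
`ai_atp`, pause mixture parameters), per-animal log-normal rate factors
(CV 5%), animal-level HR-shift (SD 3 BPM) and AI jitter (10%), and
independent diameter draws (DD 50 ± 2 px, FS 40 ± 2% with a ±1.5% paired
shift). Reproducibility uses a `numpy.random.SeedSequence` spawn tree so
each animal and condition has an independent, seed-stable stream; the same
design seed yields bit-identical cohorts. Presets: `five_strain_design`
(wild type + four variant strains, with pacing HR drops for all and raised
post-pacing AI only in the two arrhythmic variants), `treatment_design`,
and `null_design` (no pacing effect, used for type-I calibration).

## 9. What the simulator does and does not emulate

Emulated: M-mode geometry, wall contrast and Gaussian noise, beat-interval
statistics including pauses, paired BTP/ATP designs with realistic effect
sizes, per-animal heterogeneity.

Not emulated: optical artifacts (speckle, shadowing, refraction), tube
curvature and off-axis scan lines, respiration-like slow modulation,
interval autocorrelation (intervals are exchangeable by construction),
partial or missed contractions, and photobleaching. Conclusions about
detector robustness therefore transfer to real data only to the extent that
real noise resembles additive Gaussian noise at comparable contrast.

## 10. Numerical conventions

- Line sampling: `floor(L) + 1` unit-spaced samples (a 70.7 px diagonal
  gives 71 samples).
- Kymograph arrays are `(n_positions, n_frames)` float32; time stamps are
  `arange(n)/frame_rate` (frame k spans `[k, k+1)/fps`).
- All stochastic entry points take explicit integer seeds; nothing reads
  global RNG state.
- TIFF I/O stores float32 pixels with a JSON sidecar carrying frame rate,
  pixel size and provenance hash of the run configuration.
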