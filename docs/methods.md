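# Methods

This note documents the models, numerical choices and limitations behind
`hrvcam`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Synthetic cohort model

The generator produces what the analysis pipeline is designed to consume: a
cohort of subjects, each with a 300-s resting ECG and three 312-s "gameplay"
ECGs, an integer IAT severity score, and exact beat-level annotations.

**Rate modulation.** Each record starts from a fractional modulation of the
instantaneous heart rate,

    m(t) = a_LF sin(2π f_LF t + φ₁) + a_HF sin(2π f_HF t + φ₂) + n(t),

with defaults a_LF = 0.05, a_HF = 0.06, f_LF = 0.10 Hz, f_HF = 0.25 Hz (the
approximate centers of the LF and HF bands, the canonical test frequencies
for HRV spectral methods), and n(t) band-limited (≲0.5 Hz) Gaussian noise of
RMS 0.01. Phases are drawn per record. In the gameplay phase the amplitudes
are multiplied by per-class reactivity factors — HF × {1.0, 0.8, 0.6, 0.45}
and LF × {1.0, 1.0, 1.0, 1.5} for normal/mild/moderate/severe. These encode
the qualitative physiology the pipeline should recover (graded vagal
withdrawal with severity; sympathetic arousal only in the severe class) as
a learnable signal; they are configuration, not measured values. Per-subject
heterogeneity: mean RR drawn uniformly from 850 ± 75 ms and a lognormal
(σ = 0.05) multiplier applied to a subject's reactivity, so windows from one
subject are correlated and subject-grouped validation is genuinely harder
than window-shuffled validation.

**IPFM beats.** Beat k fires when (1000/meanRR) ∫₀ᵗ (1+m(τ))dτ crosses k;
the integral runs on a 4-ms grid with linear interpolation of the crossing.
This guarantees the tachogram spectrum carries the modulation frequencies,
which is what makes the spectral stages testable. Over 300 s the mean IBI
reproduces the configured mean RR within 2 %.

**Ectopics.** At the default 2/min, randomly selected beats are advanced by
25–40 % of the local RR with a compensatory pause (the next beat stays). By
construction each ectopic produces one interval shortened and one lengthened
by >20 %, the regime the 20 % filter is specified to catch.

**Waveform.** Each beat renders Gaussian P-QRS-T waves (R centered exactly
on the beat time; ectopics lose the P wave); noise adds baseline wander
(0.1 mV at 0.21/0.33 Hz), a 60 Hz line (0.05 mV) and white EMG (0.02 mV) at
fs = 250 Hz. The sampling rate is a configurable default chosen well above
the 15 Hz low-pass and sufficient for ±10 ms R timing.

**What the generator does not emulate:** respiration-driven RSA with a
variable respiratory rate, non-stationary autonomic drifts within a record,
electrode motion artifacts with impulsive morphology, atrial fibrillation
or other arrhythmias, multi-lead geometry. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and recoverability of
band-structured autonomic signatures — not clinical performance on real
ECG, which is unmeasurable here (the motivating study's subject data are
private).

## Denoising

High-pass 1 Hz and low-pass 15 Hz Butterworth (order 3 each) plus a 58–62 Hz
band-stop (order 3 per design, 6th order overall), all designed as
second-order sections and applied forward–backward. Zero-phase filtering is
chosen because R-peak *timing* feeds everything downstream; the cost is a
squared magnitude response, so the −3 dB checks in the tests address the
single-pass design. The notch bandwidth (±2 Hz) is a design choice; nothing
in the pipeline is sensitive to it as long as 60 Hz is suppressed.

## Beat detection and IBI conditioning

Pan–Tompkins with the classic stages; deliberate details:

* the derivative is a centered 5-point kernel and the 5–15 Hz band-pass is
  zero-phase, so the integrated-signal fiducial is already roughly aligned
  with the R wave; the final time is the band-passed maximum within ±50 ms;
* thresholds initialize from the first 2 s (signal estimate max/2, noise
  estimate mean/2) and adapt with the usual 0.125/0.875 updates; search-back
  fires at 1.66× the 8-beat running RR with a half threshold;
* refractory 200 ms, T-wave slope check inside 360 ms.

The 20 % ectopic filter compares each interval with the running median of
the five previously *accepted* intervals (the first five compare against the
whole-series median) — a median reference survives consecutive ectopics
that corrupt a mean. Rejected interior intervals are replaced by a natural
cubic spline over accepted points and flagged; a record with >50 % rejections
is refused. Ectopic rejection runs *before* detrending so outliers cannot
bias the trend fit; the polynomial detrend (default order 3) is applied to
the 4-Hz tachogram after cubic-spline resampling (a flag moves it to the
irregular series). The tachogram grid spans [first, last] beat time, which
is ~2 RR short of the record length — hence gameplay records are generated
at 312 s so that a full 300 s of tachogram (28 windows) is always available.

## Time-frequency analysis

The target geometry is fixed: 304 frequency bins f_k = (k+1)·0.4/304 over
(0, 0.4] Hz × 30 one-second time bins per 30-s segment, with band masks
VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4] partitioning the grid.

Both scalogram methods are implemented as weighted least-squares sinusoid
projections: for each cell, project the mean-removed segment onto
{cos 2πf_k t, sin 2πf_k t} under a window centered on the time bin and
*truncated at the segment boundary*, then normalize the projection power by
the window's in-segment mass (Σw / fs·Σw²). The windows are a 10-s Hann
(`stft`) and the Gaussian envelope of an ω₀ = 6 Morlet wavelet whose width
tracks the analysis frequency (`cwt`), with wavelet power additionally
scale-rectified (multiplied by f_k) to remove the 1/f tilt that biases tone
peaks low by about 1/(2ω₀²).

Why projections instead of padded FFT frames: the grid spacing is 1.3 mHz,
and localization to ±2 bins is part of the acceptance surface. Reflection
padding creates phase-discontinuous junctions, and a real signal's
negative-frequency image sits inside a 10-s Hann mainlobe at low
frequencies; both drag a tone's measured peak off by 3–30 bins. The
projection power of a pure tone is maximal exactly at its own frequency for
*any* non-negative window (Cauchy–Schwarz in the weighted inner product),
so boundary cells need no padding at all. For interior cells the `stft`
projection coincides with the ordinary one-sided Hann periodogram density
(the Parseval check in the tests holds within 10 %); `cwt` power is in
relative units, which cancel in the baseline normalization.

Band power integrates rows by the midpoint rule on the uniform grid —
chosen over the trapezoid rule so that VLF + LF + HF equals the total
integral exactly (the trapezoid loses the half-intervals at band
boundaries). Mean removal before projection empties the immediate vicinity
of DC, so the lowest VLF rows carry only residual slow power; white-noise
band fractions are proportional to bandwidth to within ~15 % with VLF
slightly depressed, as the tests document.

**Baseline normalization.** The 300-s resting tachogram is cut into 30-s
windows every 10 s; all time bins of all window scalograms are averaged per
frequency row into a length-304 profile (floored at 1e−8 × its maximum).
Gameplay scalograms are divided row-wise by the profile. Division (rather
than subtraction or z-scoring) makes the result a dimensionless reactivity
ratio: multiplying a subject's entire modulation scale by c scales both
numerator and denominator by c², leaving the ratio invariant — exactly the
"remove individual factors" requirement. With HF amplitude reactivity r the
expected HF-row ratio is r² (power), e.g. 0.36 at r = 0.6, which the tests
verify on the full chain.

## Dataset and validation

300 s per gameplay record → offsets 0, 10, …, 270 s → 28 windows of
304 × 30 × 1; three episodes → 84 windows per subject; at the motivating
study's scale (70 subjects) this is 5,880 windows of 9,120 values each.
IAT bands map scores to classes at 30/31, 50/51, 80/81 (the instrument's
own floor is 20, so 0–19 cannot occur in practice but remain valid labels).
Folds are dealt at the subject level, shuffled within class with one
round-robin pointer across classes, so per-class counts and totals differ
by at most one between folds and no subject's windows ever straddle a fold
boundary.

## Classifier and CAM

A compact VGG-family CNN implemented directly on NumPy: an input stem
average-pools the frequency axis by 4 (304 → 76 rows; at 1.3 mHz spacing
the spectral structure is heavily oversampled and the pooling costs no band
information), then three blocks of one 3×3 convolution (8, 16, 32 filters)
each followed by 2×2 max pooling, a global-average-pooling head and a
single linear layer to 4 classes. Inputs are log1p-transformed and
standardized by the training set's scalar mean/SD (stored with the model).
Training: softmax cross-entropy, Adam at 1e−3, batch 32, 12 epochs with
early stop once training accuracy reaches 0.995 (minimum 3 epochs), seeded
shuffling; runs are reproducible for a fixed seed and BLAS thread count.
The GAP + single-linear head is what makes original-form CAM exact:
CAM_c = ReLU(Σ_k w_ck F_k), bilinearly upsampled to 304 × 30; band
attribution fractions are the VLF/LF/HF row sums over the map total (an
all-zero map falls back to row-count shares and is flagged degenerate).
Arg-max ties resolve to the lowest class index.

Desk-scale experiment defaults: 6 subjects per class (24 subjects, 2,016
windows), 4 subject-grouped folds — with 24 subjects, ten folds would hold
out 2–3 subjects each and make per-fold metrics nearly meaningless — and
three seeded repetitions pooled by summed confusion. Class imbalance is
preserved when the caller requests it (the study-scale 15/30/23/2 split is
available); an optional class-weighting flag exists for training but is off
by default.

## Statistics

`anova_from_summary` uses the textbook identities SSB = Σnᵢ(x̄ᵢ−x̄)²,
SSW = Σ(nᵢ−1)sᵢ², F = (SSB/(g−1))/(SSW/(N−g)); `anova_oneway` recomputes
the decomposition from raw values independently, and the two routes agree
to 1e−10 relative on exact summaries (and match `scipy.stats.f_oneway`).
SSW = 0 with SSB > 0 reports F = ∞, p = 0 rather than an error. Post-hoc
pairs use Tukey–Kramer, q = |x̄ᵢ−x̄ⱼ|/√(MSW/2·(1/nᵢ+1/nⱼ)) against the
studentized-range 5 % critical value — the standard companion to a one-way
ANOVA with unequal group sizes. The embedded reference cohort summaries
(IAT and impulsivity by severity group) cover only the three non-severe
groups: an n = 2 group carries no usable within-group variance, so it is
excluded from the default comparisons (the ANOVA and Tukey functions accept
any set of group summaries, so a four-group run is a one-line call).

## Known limitations

* Synthetic realism as listed above; in particular respiration is not an
  explicit input, so HF power is a pure configured oscillation rather than
  RSA.
* The CWT scalogram's absolute calibration is arbitrary (relative units);
  only the STFT path is Parseval-consistent.
* The ectopic filter interpolates through flagged intervals; dense ectopy
  (>50 %) is refused rather than repaired.
* The classifier is deliberately small and CPU-bound; it demonstrates
  recoverability and attribution, not state-of-the-art accuracy. Nothing
  here licenses claims about classification accuracy on real cohorts.
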