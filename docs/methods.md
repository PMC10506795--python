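# Methods

## Model

A voxel's BOLD signal is modeled as a linear time-invariant system,
`y(t) = (h * x)(t) + ε(t)`, where `h` is the voxel's hemodynamic response
function (HRF), `x` the neural or vasoactive drive, and `ε` thermal noise.
All analyses in the package follow from one property of this model: the
voxel's transfer function `H(f)` is the Fourier transform of its HRF, so the
temporal shape of `h` — summarized by its time-to-peak (TTP) and full width
at half maximum (FWHM) — determines how steeply the voxel's output spectrum
decays. Faster (narrower, earlier) HRFs have flatter `|H(f)|` and relatively
more high-frequency power at rest.

### HRF parameterization

Kernels are parameterized directly by (TTP, FWHM, peak amplitude) rather
than by gamma shape/scale, because TTP and FWHM are the quantities swept and
compared. The main lobe is a gamma density whose shape `k` is solved from
the relative width FWHM/TTP (the ratio is a smooth, strictly decreasing
function of `k`; a 400-point log-spaced inversion table gives ~1e-5 relative
accuracy) and whose scale is `TTP/(k−1)`. An optional undershoot gamma,
delayed 10 s after the peak with 1.6× the main-lobe width, is subtracted
with a configurable ratio (default 0 — the spectra arguments depend only on
main-lobe timing, and whether physiological undershoots should be included
is an open modeling choice). The sampled kernel's achieved TTP/FWHM/peak are
measured from the samples (FWHM by linear interpolation at the half-maximum
crossings) and must match the request within `dt` / `2·dt`, otherwise
construction fails explicitly. Default support is 32 s; kernels must decay
below 1% of peak by their final sample.

`hrf_fourier_response` approximates the continuous-time Fourier transform by
a Riemann sum over the samples. It is the package's internal oracle: the
simulated sweep must reproduce it (tested to 1%), and the synthetic
generator uses its phase at the stimulus frequency as the ground-truth lag.

### Simulated spectra

`sweep_spectrum` convolves the kernel with `sin(2πft)` at each grid
frequency (default grid 0.01–0.5 Hz in 5 mHz steps at dt = 0.1 s; the
narrower 0.1–0.5 Hz grid is available as `METHODS_FREQUENCY_GRID`),
discards one kernel support of transient, and measures the steady-state
amplitude by complex demodulation over an integer number of cycles.
Demodulation was chosen over peak-to-peak because it is exactly checkable
against the Fourier oracle and insensitive to residual transients. Three
regimes: flat unit-amplitude stimuli, flat stimuli with peak-normalized
kernels, and stimulus amplitude 1/f (the 1/f-like spectrum of spontaneous
neural activity). One caveat found during validation: at a fixed *low*
frequency (≈0.1 Hz) the response amplitude of unit-peak kernels is not
monotone in FWHM — a wider kernel also has more area, which raises
low-frequency gain. The high/low amplitude *ratio* is monotone, and that
ratio is the mechanism the package tests.

## Synthetic subjects

The generator emulates the acquisition geometry in time only (no spatial
structure): TR 0.227 s; two 510 s resting runs; three 254 s task runs with a
14 s baseline then a 0.05 Hz sinusoidal drive; two breath-hold runs. The
printed breath-hold block schedule (27 s free + 3×6 s paced + 15 s hold +
30 s free, eight repetitions) exceeds an 8.5 min run, so the package uses
60 s blocks — 27 s free, 18 s paced (treated as free-breathing drive), 15 s
hold — ×8 plus a trailing 30 s, totalling 510 s, the only consistent reading
of eight repetitions within the run length.

Per-voxel parameters, all chosen once for realism (no per-voxel cortical
HRF distributions are published):

| parameter | fast | slow | LGN | notes |
|---|---|---|---|---|
| TTP mean (s) | 4.25 | 5.5 | 3.75 | Gaussian, sd 0.5, truncated > 0.5 |
| FWHM mean (s) | 3.0 | 4.5 | 2.5 | Gaussian, sd 0.5 |
| peak amplitude (signal units) | 1.5 | 2.0 | 1.0 | slower responses are larger |
| vascular latency mean (s) | 1.0 | 2.0 | 0.5 | sd 0.3, when coupled to class |

The 0.5 s timing spread is deliberate: real V1 voxels form a broad,
overlapping continuum of lags, and the Gaussian-window grouping procedure
presupposes a unimodal histogram. Much narrower spreads produce a multimodal
lag histogram on which a single-Gaussian fit degenerates.

Rest drive: unit-variance 1/f Gaussian noise (spectral shaping of white
noise by `f^(−α/2)`, α = 1). Thermal noise: white Gaussian, sd 2.0 signal
units per sample — the tSNR regime of 2 mm, fast-TR 7 T acquisitions, giving
localizer Z-scores comfortably above threshold for driven voxels while
keeping single-bin spectral estimates noisy. Breath-hold runs: the hold
boxcar convolved with the sign-reversed canonical response, peak-normalized,
shifted per voxel by its vascular latency, scaled by 3 signal units, plus
thermal noise. Latency is coupled to HRF class by default; decoupling pools
the three latency distributions to emulate the regime where breath-hold
timing fails to track task-response timing.

What the generator does **not** emulate: spatial autocorrelation, motion,
cardiac/respiratory physiological noise, and high-frequency vascular noise
concentrated in venous voxels. Consequences: recovery rates here are upper
bounds on real-data performance; hemisphere-style splits guard against
nothing in synthetic mode (tags are arbitrary); and the fALFF group
difference has the sign the band-ratio definition implies for noiseless-tail
spectra (fast voxels *lower*), whereas real venous high-frequency noise
could invert it.

## Analysis choices

- **Localizer.** OLS on {1, sin, cos} at the stimulus frequency, time
  measured from stimulus onset (the first retained sample sits at
  `ceil(14/TR)·TR ≈ 14.074 s`, and ignoring the offset biases every lag by
  74 ms). F statistic of the sine+cosine pair; Z is the upper-tail normal
  quantile of the F survival probability; perfect fits are flagged
  `saturated` with a large finite Z. No drift regressors — detrending
  belongs to preprocessing.
- **Phase.** For `r(t) = A·sin(2πf t − φ)`, `φ = atan2(−β_cos, β_sin)` and
  lag = `φ/(2πf)` wrapped into [0, 1/f). Positive lag = delayed response.
- **Lag histogram.** 30 equal-width bins over the lag range;
  `a·exp(−(x−b)²/2σ²)` fit by bounded least squares with four deterministic
  starts (moment-, peak-, and span-based) keeping the lowest SSE — a single
  start can pin against the bounds on broad or multimodal histograms.
  FWHM = 2√(2 ln 2)·σ. Fast/slow windows are the closed intervals
  [b−FWHM/2, b−FWHM/6] and [b+FWHM/6, b+FWHM/2] (each FWHM/3 wide,
  symmetric, disjoint). Grouping runs on cortical voxels only; LGN voxels
  are an anatomically defined group, localizer-thresholded like cortex.
- **Multitaper PSD.** Five unit-norm DPSS tapers at NW = 3 on the
  mean-removed post-14 s segment, zero-padded to the next power of two
  (2185 → 4096 samples for a default resting run, giving ~1.08 mHz bins and
  ~465 bins below 0.5 Hz). One-sided density normalization: the spectrum
  integrates to the series variance.
- **Slope / aperiodic fit.** Slope: OLS of log₁₀ power on *linear*
  frequency over (0, 0.2] Hz (consistent with the log-scaled regressand of
  the aperiodic model; a linear-power option exists). Aperiodic:
  `y = b − x·log₁₀ F` over (0, 0.5] Hz by Levenberg–Marquardt; the model is
  linear in (b, x), so the fit must coincide with closed-form log-log
  regression — the suite enforces agreement to 1e-6. DC is excluded; zero
  power is floored at 1e-300 before logs.
- **ALFF / fALFF.** Ideal FFT-domain band-pass (bit-reproducible), power
  `P = |FFT|²/N`, ALFF = band mean of √P over 0.01–0.08 Hz; fALFF = ratio of
  that mean to the 0.01–0.25 Hz mean. The band-mean convention makes fALFF
  exactly 1 for flat-magnitude spectra and `n_wide/n_low` for band-limited
  ones; the classical sum-based ratio is available via `sum_based=True`.
- **Breath-hold latency.** Reference = mean of demeaned voxel series with
  zero-lag Pearson r > 0.25 against the regressor. Both series linearly
  interpolated to 100 ms; normalized cross-correlation over ±15 s (wide
  enough for physiological delays, short of the 60 s block alias); ties
  break toward the smallest |lag|.
- **Classification.** "Bootstrap" = repeated stratified random 80/20
  train/validate splits (not resampling with replacement), standardization
  fit on the training fold only, RBF SVM with C = 10 and scikit-learn's
  `gamma="scale"` (= 1/(n_features·Var X)). SVR: same kernel and C,
  ε = 0.1, on lags re-expressed about their median and clipped to ±3 s.
  Reports: mean and 95% percentile interval over splits. The
  full-spectrum feature set (`build_spectrum_matrix`) uses all PSD bins
  ≤ 0.5 Hz; its count depends on the padded resolution and is reported,
  not forced.

## Problem sizes

Tests run subjects of 20–100 voxels per class with 25–200 splits; the
acceptance script uses 150 voxels per class and 200 splits. These sizes give
stable estimates (classification accuracy varies by ~1 point across seeds)
while keeping any single check in seconds.

## Known limitations

- Real-data mode supplies I/O and the stage functions but no preprocessing;
  inputs are assumed motion-corrected and physiologically denoised.
- The aperiodic model has no periodic ("peak") components; strong
  oscillatory peaks would bias both slope and exponent.
- The latency estimator's tie-break toward zero compresses extreme latencies
  at low SNR (visible in example 04), a property of argmax cross-correlation
  on smooth waveforms rather than of the implementation.
- Synthetic hemisphere tags are arbitrary, so hemisphere-style splits test
  the mechanics of group-wise validation, not spatial generalization.
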