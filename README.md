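# hemospec

Spectral signatures of local hemodynamic response timing in fast fMRI.

The BOLD signal is a blurred, delayed image of neural activity: each voxel's
hemodynamic response function (HRF) acts as a low-pass filter whose
time-to-peak (TTP) and width (FWHM) vary across the brain with local
vasculature. Treating the voxel as a linear time-invariant system,
`y(t) = (h * x)(t)`, a *faster* HRF (smaller TTP and FWHM) has a flatter
transfer function |H(f)| and therefore passes relatively more high-frequency
power — so the shape of a voxel's resting-state power spectrum carries
information about its hemodynamic speed, without any task. This matters for
anyone interpreting timing in fMRI: apparent "sequences of activation" can be
purely vascular.

`hemospec` implements the complete analysis around this idea:

- **HRF kernels** (`hemospec.hrf`) — double-gamma kernels parameterized
  directly by (TTP, FWHM, peak amplitude), with their analytic Fourier
  response `H(f)` as a built-in oracle.
- **Simulated BOLD spectra** (`hemospec.simspec`) — convolve an HRF with
  sinusoidal drives across 0.01–0.5 Hz and record the steady-state response
  amplitude, under flat, peak-normalized, and 1/f-weighted stimulus regimes.
- **Synthetic subjects** (`hemospec.synth`) — resting (8.5 min), visual-task
  (254 s, 0.05 Hz sinusoidal drive after a 14 s baseline), and breath-hold
  (eight 60 s blocks) runs at TR = 0.227 s, for voxels drawn from fast-cortical,
  slow-cortical, and LGN-like HRF families with 1/f neural drive and thermal
  noise — with exact per-voxel ground truth.
- **Task phase mapping** (`hemospec.task_phase`) — sine/cosine GLM localizer
  (F→Z, threshold 2.5), phase lag from `atan2` of the coefficients, Gaussian
  fit to the lag histogram, and fast/slow windows
  `[b − FWHM/2, b − FWHM/6]` / `[b + FWHM/6, b + FWHM/2]`.
- **Resting-state spectral features** (`hemospec.spectral`) — five-taper
  multitaper PSD; slope of log₁₀ power below 0.2 Hz; aperiodic fit
  `y = b − x·log₁₀(F)` below 0.5 Hz; ALFF (band mean of √(|FFT|²/N) in
  0.01–0.08 Hz) and fALFF (its ratio to the 0.01–0.25 Hz band); within-run
  z-scoring and run averaging; rank-sum group comparisons.
- **Breath-hold latency** (`hemospec.breathhold`) — task regressor (hold
  boxcar ⊛ sign-reversed canonical response), global reference from voxels
  with r > 0.25, per-voxel latency by cross-correlation on a 100 ms grid.
- **Speed classification** (`hemospec.classify`) — three-class RBF-kernel SVM
  (C = 10, γ = 1/(n_features·Var(X))) over repeated stratified 80/20 splits,
  plus ε-insensitive SVR of relative lag within ±3 s.
- **Pipeline** (`hemospec.pipeline`, `hemospec.cli`) — end-to-end orchestration,
  NIfTI/TSV/JSON I/O, and a thin `hemospec` command-line interface.

## Worked example

Sweep the packaged HRF family and print how much 0.2 Hz power each kernel
retains relative to 0.05 Hz (`python examples/01_hrf_spectra.py`):

```
HRF      TTP (s)  FWHM (s)  A(0.2)/A(0.05)
hrf1        3.50      2.50           0.434
hrf2        4.00      3.00           0.314
hrf3        4.50      3.50           0.221
hrf4        5.00      4.00           0.154
hrf5        5.50      4.50           0.106
hrf6        6.00      5.00           0.074
```

The fastest kernel keeps 43% of its low-frequency response amplitude at
0.2 Hz; the slowest keeps 7% — a six-fold spread that survives peak
normalization and 1/f stimulus weighting. Classifying voxels from the four
resting-state features (`python examples/05_classification.py`):

```
four spectral features : 94.4% (95% CI 83.3%-100.0%)
breath-hold latency    : 56.0%
label-permutation null : 32.4% (chance = 33.3%)
```

The spectral features recover the hidden hemodynamic class of 94% of held-out
voxels; a single breath-hold latency predictor does far worse, and permuting
labels collapses accuracy to chance. The other examples walk through phase
mapping (`02`), the feature comparisons (`03`), and latency mapping (`04`).

A thin CLI wraps the same functions for shell use, e.g.:

```bash
hemospec run-all --seed 1 --n-per-class 30 --bootstraps 200 --out out/
hemospec simulate --ttp 4.0 --fwhm 3.0 --out spectrum.tsv
```

## Real data

The analysis functions operate on plain voxel time series, so preprocessed
4D NIfTI runs can be analyzed by composing the stages directly (see
`hemospec.pipeline.load_bold_run`). Motion correction, slice timing, and
physiological-noise removal are assumed to have been done upstream.
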