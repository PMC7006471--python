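# Methods

## Model

A neurofeedback (NF) score series y(t), sampled at 4 Hz over a session,
is modelled as a linear functional of a structured EEG feature tensor:

    y(t) ≈ ⟨X_c(t), α⟩ = Σ_m Σ_b X_c(t, m, b) · α(m, b)

where X_c(t) ∈ ℝ^{M×B} collects band powers per feature row m (an
(electrode, delay) pair) and frequency band b, and α is the *activation
pattern* to be learned.  The target y can be the EEG score y_e, the
fMRI-derived score y_f, or the hybrid score y_c = y_e + y_f (both
standardized before summation).

The pattern is estimated by penalized least squares,

    α̂ = argmin_α Σ_t ½ (y(t) − ⟨X_c(t), α⟩)² + λ‖α‖_21 + ρ‖α‖_1,

with ‖α‖_21 = Σ_m √(Σ_b α_mb²).  The group term drives whole
(electrode, delay) rows to zero — only a few scalp sites should carry
task information — while allowing the surviving rows to stay smooth
across the overlapping bands; the ℓ1 term then removes irrelevant bands
within surviving rows.  Both effects produce *exact* zeros, so sparsity
statistics count zeros without thresholds.

## Design tensor

* **Grid.** One output row per 0.25 s over the whole session; a 320 s
  session gives T = 1280.  Row i summarises the window ending at
  (i+1)·0.25 s and extending 2 s into the past.  The first 7 rows, where
  less than 2 s of signal exists, use the available prefix with the same
  taper; they are counted in `n_prefix` metadata.  This keeps the grid
  length exactly 4 Hz × duration.
* **Band powers.** A single Hamming-tapered periodogram per window
  (density scaling, no detrending); band power is the mean PSD over the
  FFT bins whose centre frequency falls in [low, high], edges inclusive.
  Bands default to width 3 Hz, overlap 1 Hz, spanning 8–30 Hz: starts
  step by 2 Hz from 8, a band is kept while its upper edge is ≤ 30,
  giving exactly ten bands [8,11] … [26,29].  (The nominal upper limit of
  30 Hz cannot be hit exactly by this lattice; the construction stops at
  29 Hz.)
* **Hemodynamic delays.** The BOLD response trails neural activity by
  seconds, so X_0 is convolved (causally, along time) with canonical
  double-gamma response kernels: a gamma density with unit dispersion and
  mode at the peak parameter (3, 4 or 5 s) minus 1/6 of an undershoot
  gamma with mode at 16 s, sampled at 4 Hz over 32 s and peak-normalized
  to 1.  Full design: [X_0; X_3; X_4; X_5], M = 4E.  Delayed-only
  (for predicting y_f): M = 3E.  X_0-only is kept as an ablation mode.
* **Preprocessing.** An *active set* of electrodes can be kept (the
  shipped 28-channel default drops the outer ring, which rests against
  the scanner bed; the exact membership is a config list, not a
  contract).  Per-column outliers beyond mean ± 3·std are clipped; the
  statistics are computed on the learning session and stored so test
  sessions are clipped with the same bounds (no leakage).  Annotated bad
  samples are removed jointly from the design and its score series.

## Optimization

FISTA with gradient step 1/L on the data term followed by the proximal
map of the penalty, plus the standard momentum extrapolation
t_{k+1} = (1 + √(1+4t_k²))/2.  Details:

* L is the largest eigenvalue of X_V^T X_V (X_V the T × MB unfolding),
  computed by power iteration to 1e-8 relative tolerance — M·B can reach
  ~1120, so no dense SVD is formed.
* The prox of λ‖·‖_21 + ρ‖·‖_1 is closed form: soft-threshold each entry
  by ρ, then shrink each row by (1 − λ/‖row‖₂)⁺.  Setting λ = 0 or ρ = 0
  recovers the plain ℓ1 or group prox.  (The λ = 0 branch returns the
  soft-threshold directly, which also avoids row-norm underflow for
  subnormal inputs.)
* Initialization is α = 0; the solver accepts a warm start, which the
  λ-selection path uses.
* Stopping: 2000 iterations or relative objective change below 1e-8,
  whichever first.  The test suite verifies the final objective against
  an independent Davis–Yin splitting solver to 1e-6 relative.

## λ selection

The learning session is split K = 50 times (tests and the acceptance
study use K = 25 to halve runtime) into 90% training / 10%
cross-validation index sets, drawn uniformly at random without
replacement.  The splits ignore temporal autocorrelation — adjacent
0.25 s samples are strongly dependent, so the CV error is optimistic as
an absolute number; it is only used *comparatively* across λ.  For each
λ of a 15-point linear grid from 100 to 3000 (spacing unstated in the
protocol; linear is the plainest reading), models are fitted on every
training set and the criterion Σ_k [NMSE_train,k + NMSE_cv,k] is
accumulated.  Scanning proceeds in ascending λ and stops after the first
λ whose mean nonzero count over splits falls below 2 (larger values
could only produce null models).  The argmin wins; criterion ties within
1e-9 relative go to the larger λ, favouring sparsity.

## NF scores

* y_e(t) = −PSD_[8–30](Lap(C3, I_t)): the Laplacian (C3 minus the mean of
  its neighbours; default montage FC3/CP3/C1/C5, configurable) sharpens
  the signal over the right-hand motor area, and the minus sign makes
  event-related desynchronization push the score in the same direction
  as the fMRI score.  The same windowing code path as the design tensor
  guarantees identical grids.
* y_f arrives at 1 Hz, is linearly interpolated to the 4 Hz grid and
  smoothed with a Savitzky–Golay filter (window 9 samples = 2.25 s,
  cubic) — parameters chosen to remove the resampling staircase without
  flattening 20 s block responses; they are arguments, not constants.
* Standardization uses population (1/n) moments per session; y_c is the
  sum of the two standardized series.

## Synthetic sessions

The generator emulates the statistical structure the method assumes:

* 8 alternating blocks of 20 s rest / 20 s motor imagery (rest first),
  320 s total, EEG at 250 Hz on a reduced 8-channel 10-20 montage around
  C3.
* Each channel is a sum of sinusoidal alpha/beta oscillators whose
  envelope is scaled down by a *task modulation depth* during imagery
  (ERD; strongest at C3, depth 0.5) plus white sensor noise (1 µV).
  Each oscillator's envelope also waxes and wanes spontaneously —
  Gaussian fluctuations of relative sd 0.5 with ~2 s correlation time,
  independent across oscillators, as in resting EEG.  These spontaneous
  fluctuations matter statistically: without them every channel's band
  power would be driven by the same task envelope, the design columns
  would be near-collinear, and no method could identify *which*
  electrode generated a score.
* Recovery targets are y(t) = ⟨X(t), α*⟩ + ε with a 5-cell ground truth
  on five distinct (electrode, delay) rows; weights are sized inversely
  to the underlying rhythm's amplitude so every row carries comparable
  signal.  The noise sd is set from the clean signal for an SNR of 10.
* fMRI-like scores are the block indicator convolved with the HRF,
  downsampled to 1 Hz, plus noise.

What the generator does **not** emulate: volume conduction and lead
fields (channels are independent sources), 1/f background spectra, MR
gradient and ballistocardiogram artifacts, non-stationary task strategy
drift.  Passing recovery tests therefore show the estimator works when
its model assumptions hold — they say nothing about artifact robustness
on scanner data.

## Study sizes used in tests and the acceptance script

Recovery: one learning + one held-out 320 s session (T = 1280, E = 8,
M = 32, B = 10), λ selected with K = 25 splits over the 15-point grid.
Ablation: 10 repetitions of learning/test pairs with targets generated
from delayed features only, fixed λ = 100, ρ = 1500 for both designs.
Solver cross-checks: 100 random 5×4 prox instances (λ, ρ ∈ [0,2]) against
Douglas–Rachford; 20 random instances with M·B ≤ 40 against Davis–Yin.

## Known limitations

* ρ is fixed (1500) and never estimated; its appropriate scale depends
  on the units of the design and scores.
* The CV splits are random points, not contiguous blocks; with strongly
  autocorrelated scores a blocked scheme (configurable) would be more
  conservative.
* The prefix windows (first 2 s) have coarser spectral resolution than
  the rest of the grid.
* Band power is a single-taper estimate; no multitaper variance
  reduction.
* One model per subject and session; no pooling across subjects.
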