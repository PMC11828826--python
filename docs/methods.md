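# Methods

`emovmd` implements a frequency-domain EEG emotion-analysis pipeline:
synthetic session generation, artifact cleanup, variational mode
decomposition (VMD), sliding-window band-power features, and a
multi-classifier evaluation with ablation and feature-attribution reports.
This note records the models, the parameters that matter, and the design
choices made where more than one defensible option existed.

## The decomposition model

VMD represents a signal f(t) as a sum of K intrinsic mode functions
u_k(t) = A_k(t) cos(φ_k(t)) — AM-FM oscillations with non-negative
envelope, nondecreasing phase, and compact spectral support around a center
frequency ω_k.  The modes minimize the total estimated bandwidth (the
squared H¹ norm of each demodulated analytic signal) subject to
Σ_k u_k = f.  The constraint is relaxed with a quadratic penalty α and a
Lagrange multiplier λ, and the saddle point is found by ADMM entirely in
the frequency domain: each mode update is a Wiener filter
û_k ← (f̂ − Σ_{i≠k} û_i + λ̂/2) / (1 + 2α(ω − ω_k)²) applied to the
current residual, each center frequency moves to its mode's spectral
centroid over [0, ∞), and λ̂ ascends by τ·(f̂ − Σ û_k) per sweep.

Solver parameters (all exposed in `VMDConfig`):

| parameter | default | why |
|---|---|---|
| K | 5 | five modes, one per canonical EEG band in practice |
| α (bandwidth penalty) | 2000 | standard practice; sharp enough to isolate tones separated by a few Hz at 128 Hz |
| τ (dual step) | 0 | exact-reconstruction pressure off; robust when the residual is noise |
| tol | 1e-7 | relative spectral change summed over modes, floored at 1e-14 |
| max_iter | 500 | two-tone problems converge in < 10 sweeps; noisy EEG windows in ~50–200 |
| init | uniform | ω_k start at 0.5·k/K normalized (k = 0…K−1), so the first mode can capture near-DC content; `zero`, `random` (seeded) and an explicit frequency list are also available |

Numerical choices: updates run on the non-negative half-spectrum (the
analytic-signal convention); the signal is mirror-extended by half its
length on each side before the FFT and cropped after inversion, which
suppresses boundary discontinuities.  Residual reconstruction error under
τ = 0 concentrates entirely in the first/last few percent of samples (the
mirror junctions); interior error on noiseless two-tone input is below
0.5 %.  Modes are returned sorted by **ascending** center frequency, so
`IMF1` is the slowest oscillation.  The descending convention — under which
the low-frequency mode is the highest-numbered IMF — is available as
`mode_order="descending"` in feature extraction; the two are mirror images
column-wise.

## The synthetic paradigm generator

Real recordings for this task are not publicly deposited, so the generator
produces sessions with the statistical structure the analysis assumes,
together with the ground truth needed to verify every stage.  A session
follows a two-phase stimulus paradigm at 128 Hz on 32 channels (10–20
montage): per phase, 10 s relax, then for each of happy/sad/fear a block
of three 5 s images, with 5 s relax between emotions (65 s per phase).
Segment boundaries are half-open [start, end) in samples with the origin
at sample 0.

Injected structure, per channel:

- **Class components.** Each emotion contributes AM-FM oscillations
  (carrier inside a named band, sinusoidal amplitude modulation, depth 0.2
  at 0.25 Hz) during its own segments only.  Defaults: all classes share
  Theta 6 Hz/1.5 µV, Alpha 10 Hz/1.5 µV, Beta 21 Hz/1.2 µV and Gamma
  35 Hz/0.8 µV components, so every decomposition mode is occupied; the
  *discriminative* signal is a Delta 2 Hz component with amplitude 2 µV
  (fear), 3.5 µV (happy), 5 µV (sad).  The known-best feature is therefore
  the Delta power of the lowest-frequency mode (`IMF1_Delta` ascending,
  `IMF5_Delta` descending).  Three details matter for clean recovery:
  the AM envelope phase is redrawn for every segment occurrence (a global
  envelope would be phase-locked to the periodic stimulus schedule and
  leak class identity into every band); every class keeps a 2 Hz carrier
  strong enough to anchor the lowest mode's center frequency (otherwise
  that frequency relocates per class and the renormalized Wiener-filter
  weights spread class information across all 25 cells); and each
  component projects through a fixed signed per-channel topography
  (normalized to unit mean square, so channel-averaged band powers scale
  exactly with amplitude²) — dipolar sources project with either polarity,
  and a uniform same-sign topography would mimic an ocular source for the
  frontal-correlation ICA criterion.
- **Background noise.** Independent 1/f (pink) noise per channel at 2 µV
  standard deviation, plus four shared pink sources mixed across channels
  at low rank (0.6 gain) so that ICA has a meaningful mixing structure.
- **Drift.** A degree-2 polynomial per channel, 20 µV peak — exactly the
  trend class that Savitzky–Golay subtraction is built to remove.
- **Blinks.** Squared-cosine bumps, 75 µV, 0.4 s, ~10/min, at unit gain on
  Fp1/Fp2 with 0.3 leakage onto the remaining frontal (F*) channels —
  a spatially stereotyped, super-Gaussian source that FastICA isolates.

The effect sizes are configuration, not claims about any real dataset: the
generator does not model cortical geometry, volume conduction, inter-subject
variability, non-stationary noise, or line interference.  Passing tests
show the *pipeline* recovers what was injected under these conditions, not
that real EEG would behave as cleanly.  One cross-talk effect is worth
knowing: because Wiener-filter tails overlap, a strong class-dependent tone
leaks a class-dependent (if tiny) power into neighbouring (IMF, band)
cells, so several ablation cells can saturate together; the planted cell is
asserted to *attain* the single-cell maximum rather than to exceed all
others strictly.

## Preprocessing

1. **Zero-phase bandpass, 0.5–45 Hz.**  A single windowed-sinc (Hamming)
   FIR of odd length, ~3.3·fs/transition taps (845 at the default 0.5 Hz
   transition), applied forward-backward (`filtfilt` with odd-reflection
   padding of 3 filter lengths).  The Hamming design gives ≳50 dB
   single-pass stopband attenuation, > 100 dB after the double pass; the
   signal must exceed three filter lengths.
2. **Savitzky–Golay detrending**, frame 127, order 5, per channel: the
   smoothed reference reproduces polynomials up to degree 5 exactly, so its
   subtraction removes such trends to numerical precision away from the
   first/last half-frame (edge behaviour is design-dependent and excluded
   from exactness claims).
3. **ICA ocular removal.**  Seeded FastICA with as many components as
   channels; components whose absolute Pearson correlation with the mean of
   Fp1/Fp2 reaches the threshold (default 0.7) are zeroed before
   reconstruction.  The threshold replaces visual component inspection with
   an automated, testable criterion.  Note its floor: a component aligned
   with a single frontal channel correlates 1/√2 ≈ 0.707 with the
   two-channel frontal mean, so on artifact-free data with strong private
   per-channel noise the default 0.7 threshold has a nonzero false-positive
   rate; raise it (or widen the frontal set) if that matters.  If nothing is flagged the input is
   returned unchanged, which also makes the step idempotent on clean data.
   Rank-deficient channel covariance (e.g. a duplicated channel) is
   rejected before decomposition.

## Features

Windows slide from sample 0 with hop = length × (1 − overlap) (default 3 s,
50 %); trailing partial windows are dropped, as is any window that straddles
a label boundary or contains relax samples — mixed-emotion windows are never
emitted.  Within each window, every channel is decomposed into K = 5 modes
and each mode's power in Delta [0.5, 4), Theta [4, 8), Alpha [8, 12),
Beta [12, 30) and Gamma [30, 45] Hz is computed from the rectangular-window
DFT with the 1/N² mirror-bin normalization: band powers of a window sum to
its mean squared amplitude (exact Parseval closure, tested to 1e-9
relative).  This normalization is deliberately window-length-invariant;
an unnormalized power sum would scale with N and make the window-length
sweep incomparable.  Gamma is capped at the 45 Hz bandpass edge: nothing
above it survives preprocessing, and closure checks are run on
band-limited windows for the same reason.  The 25 band powers are averaged
across channels into one feature row per window (per-channel and
single-channel policies are available); rows carry the window start, label
and the id of the stimulus segment they came from.

## Evaluation

Stratified 80/20 train-test split; 6-fold stratified, shuffled
cross-validation on the training split gives the validation accuracy; the
model refit on the whole training split is scored on the held-out 20 %
(accuracy, macro precision/recall/F1, 3×3 confusion matrix).  Classifiers:
KNN (k = 5, Euclidean), SVM (RBF, C = 1, γ = 'scale'), decision tree (Gini,
unlimited depth), random forest (100 trees, √25 = 5 features per split).
The default split is window-level; because 50 %-overlapping windows share
samples, this can leak information between train and test within a
stimulus segment — `grouping="by_trial"` keeps all windows of a segment on
one side and is the rigorous alternative.  The ablation table retrains on
every (IMF, band) feature subset — 5 single-IMF rows × 5 single-band
columns plus "All IMFs"/"Combined features" — on one shared training split.

**Attribution.**  Two methods share one report schema (per-feature,
per-class mean absolute attribution plus a ranking): `tree_path`
decomposes tree-ensemble class probabilities along each decision path,
crediting every split feature with the change in the node value (averaged
over trees); `permutation` measures the mean absolute shift in predicted
class probabilities over 20 seeded shuffles of one feature column.  On a
strongly planted signal both rank the same feature first; the tree-path
method is exact for the model's own additive path structure, while
permutation is model-agnostic and slower.

## Reproducibility and problem sizes

One global seed derives per-stage seeds by hashing the stage name
(CRC32-based, < 2³¹), so `run_all` executed twice under one seed produces
bit-identical artifacts (verified by SHA-256 checksums in the run
manifest).  Functional tests run on two-phase default sessions (~50
emotion windows); the end-to-end classification, ablation, permutation-control
and attribution checks use a 13-phase session (~320 windows of 3 s at 50 %
overlap, 32 channels), the package's chosen problem size for a stable
three-class evaluation.  The EDF writer emits 16-bit, 1 s data records and
therefore requires an integer sampling rate and whole-second recordings;
round trips are exact to one quantization step of the per-channel physical
range, and CSV round trips are exact to float precision.

## Known limitations

- The generator's class effects are stationary within segments and
  identical across channels; no spatial topography of emotion effects is
  modeled.
- VMD mode count is fixed (no automatic K selection); modes beyond the
  number of distinct oscillations share energy near the strongest
  remaining component.
- Reconstruction error concentrates at window edges (mirror-extension
  junctions); applications needing exact edges should pass τ > 0.
- The window-level split mirrors common practice but can overstate
  accuracy; use trial grouping for leakage-free numbers.
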