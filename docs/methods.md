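# Methods

This note records the models implemented by `vims_eeg`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not establish.

## Signal model of the synthetic corpus

Each non-mastoid channel is

```
x(t) = Σ_band A_band(region, m(t)) · sin(2π f_band t + φ) + pink(t) + white(t)
```

with one sinusoid per rhythm band (delta 0.5–4, theta 4–8, alpha 8–13,
beta 13–30 Hz), frequency drawn uniformly inside the band (5 % edge
margin, to keep single-band configurations unambiguous under a
periodogram oracle) and phase uniform.  The amplitude interpolates
linearly between the normal-state and sickness-state entries of a
per-(region, band) table as the latent sickness level `m(t) ∈ [0, 1]`
rises.  The default table encodes the regional pattern reported for
VIMS: frontal/temporal broadband increase, central/parietal/occipital
alpha decrease, global beta increase.  Mastoids carry only noise, so
re-referencing is exercisable but neutral.  Pink noise is spectrally
shaped white noise (amplitude ∝ 1/√f, normalized to a target sd of 2 µV;
white noise sd 1 µV) — a realistic EEG background without biophysical
modelling.

The latent trajectory is a logistic ramp
`m(t) = peak / (1 + exp(−slope(t − onset)))` with default onset 56 s and
slope 0.15 /s, matching the onset timing the study describes; `m(0) ≈
2·10⁻⁴`.  SSQ item scores are Binomial(3, m_end) draws: an ordered
categorical whose mean rises monotonically with the latent level, with
forced floor (m = 0 → all zeros) and ceiling (m = 1 → all threes).
Corpus severities vary per (subject, video) on U(0.6, 1.0) so SSQ totals
carry variance.  All randomness derives from
`SeedSequence(seed, spawn_key=(subject, video, stream))`, making every
corpus byte-for-byte reproducible and each recording independent.

**What this generator does not emulate:** volume-conducted spatial
correlation between channels, non-stationary artifact families
(blinks/EMG beyond the rank-1 injector used in preprocessing tests),
inter-subject spectral idiosyncrasies, and any genuine physiological
coupling between EEG and questionnaire behaviour.  Passing the
end-to-end tests therefore demonstrates that the pipeline recovers the
structure it was told to generate — not that the trained networks would
reach the same figures on clinical recordings.

## Preprocessing

* **Filter.** Zero-phase Butterworth band-pass (order 4 per pass,
  applied forward–backward with `sosfiltfilt`), default 0.5–50 Hz.  A
  windowed FIR with a transition width proportional to the edge
  frequency was considered and rejected: at a 0.5 Hz edge it needs
  >10⁴ taps, longer than a 5 s epoch.  The IIR-forward-backward filter
  has exactly zero phase, unity passband gain (10 Hz gain 0.9998
  measured) and > 35 dB attenuation at 80 Hz.  The two acquisition-time
  passes (0.1–100 Hz then 0.5–50 Hz) compose to the narrower band and
  are implemented as the single 0.5–50 Hz pass.
* **PCA artifact removal.** Channel-covariance eigendecomposition; a
  component is removed iff its variance share > 0.35 **and** the excess
  kurtosis of its time course > 8.  Both thresholds are exposed; they
  target sparse, high-amplitude, non-Gaussian transients while leaving
  oscillatory rhythms (kurtosis ≈ 0 or negative) untouched.  Removal is
  a projection, so total variance never increases.
* **Re-referencing.** Each channel minus the mean of M1/M2; the
  mastoids are dropped.  If mastoids are absent the call *fails* unless
  the caller explicitly requests the common-average fallback — a silent
  fallback would change results invisibly.
* **Epoching.** Non-overlapping, half-open windows `[t, t+w)` from time
  zero; the trailing partial window is discarded (consistent with the
  published 4800/2400/2000 counts for 5/10/12 s windows).

## Wavelet packet features

* Depth 8 with db4 (the study's configuration), periodic boundary.
  Signals are zero-padded at the end to a multiple of 2⁸ (5000-sample
  epochs → 5120) and reconstructions truncated back; with the
  orthonormal periodized filter bank, Parseval and perfect
  reconstruction are exact (≤ 10⁻⁸ relative, used as test oracles).
* Node frequency ordering: the natural (filter-bank) index of the node
  with frequency rank r is the binary-reflected Gray code of r, because
  every high-pass split mirrors its subtree's spectrum.  The inverse
  Gray code therefore maps natural index → rank; verified against a
  tone-sweep oracle for levels 1–6 and against PyWavelets'
  frequency-ordered traversal.
* Band → node rule: a leaf is selected iff its frequency-ordered
  passband centre lies in the half-open band interval.  At depth 8 and
  500 Hz the nodes are ≈ 0.977 Hz wide (delta spans 3 nodes, theta 4,
  alpha 5, beta 18).
* **Known limitation:** db4's short support gives wide node transition
  bands; a pure 10 Hz tone keeps ≈ 81 % of its energy in the alpha
  reconstruction, leaking ≈ 10 % into theta and ≈ 7 % into beta.  This
  is intrinsic to the wavelet choice, not to the implementation (the
  coefficient trees match PyWavelets to 10⁻¹⁰), and does not prevent
  band contrasts from separating the states.
* **Pooling.** Each of the 40 streams (8 channels × {original, δ, θ, α,
  β}) is reduced to an RMS envelope over 0.1 s frames (10 frames/s →
  100 frames per 10 s window).  Arithmetic-mean pooling would average
  the zero-mean oscillations to ≈ 0 and destroy exactly the band
  amplitude information the model needs; RMS pooling keeps it and
  bounds the GRU sequence length so 50-epoch CPU training takes minutes.
* Per-stream z-scoring with statistics frozen on the training split
  (sigmoid/tanh networks need scaled inputs; the statistics travel with
  the checkpoint).

## Networks and training

* The GRU cell follows the convex-blend update
  `h' = (1−z)⊙h + z⊙h̃` exactly; the narrative variant "h' = h + h̃"
  that sometimes appears alongside it is not a convex combination and is
  not implemented.  Weights act on the concatenation `[h, x]`; biases
  are included (standard practice) but the verification tests exercise
  the bias-free configuration against an independently coded scalar
  recursion (10⁻¹⁰) and the full BPTT against finite differences
  (~10⁻⁶ relative).  No deep-learning framework is used: the cell *is*
  the model under test, and a NumPy implementation keeps training
  bit-deterministic under a fixed seed.
* Architectures are fixed: classifier Dense40/ReLU (time-distributed) →
  GRU32/tanh → Dense16/ReLU → Dense8/ReLU → Dense1/sigmoid; predictor
  Dense40/ReLU → GRU32/tanh → Dense32/16/16/8 (ReLU) → Dense1/sigmoid.
  The 40-unit input layer is read as a per-frame transform — the only
  reading consistent with a recurrent layer following it — and the GRU
  feeds its final hidden state to the dense head.
* Adam with lr 5·10⁻⁵, β₁ 0.9, β₂ 0.999, decoupled weight decay 10⁻⁸,
  batch 4, 50 epochs; probabilities clipped at 10⁻⁷ inside the
  cross-entropy.  Splits are 70/15/15 grouped by subject (no epoch of a
  test subject is ever seen in training).
* The predictor's resting reference R is the mean feature frame over
  the subject's normal-state epochs, broadcast over time (exposed as a
  strategy object so, e.g., an autoencoder reconstruction could be
  swapped in).  Targets are on the normalized SSQ scale
  (total / 235.62); trajectory-corpus epochs use the mean latent level
  over the window, and predictions are rescaled by 235.62 for reporting
  in SSQ units.

## Problem sizes used by tests and the acceptance script

Generating the full study-scale corpus (25 × 20 × 2 × 120 s = 1,200
recording-minutes) is unnecessary for verifying the pipeline; the
shipped experiments use scaled-down corpora chosen once:

* separable classifier corpus: 7 subjects × 3 videos × 60 s per state,
  10 s windows (252 epochs; 5 train / 1 val / 1 test subjects);
* zero-contrast control: same shape, 5 s windows (504 epochs);
* trajectory corpus: 7 subjects × 2 videos × 120 s, 10 s windows
  (336 epochs), prediction stride 2 s on the held-out subject.

Training settings are never scaled.  With these sizes the classifier
reaches perfect held-out separation on the default amplitude table, the
zero-contrast control stays at chance (≈ 0.54), and the predictor
recovers the latent trajectory with SROCC ≥ 0.8 and an onset-timing
error of a few seconds — the window-end timestamping biases the detected
rise a few seconds late by construction.

## Numerical and degenerate-input conventions

Half-open band intervals resolve node-boundary ties; the EDF writer
uses symmetric per-channel physical ranges so 0 µV maps to digital 0
(round-trip error ≤ one quantization step); all-zero recordings pass
through PCA unchanged with no components removed; correlation metrics
raise on constant inputs instead of returning 0; undefined rates (empty
class) are reported as missing, not as 0.  Sensitivity/specificity are
always reported under both positive-class conventions: published
confusion tables in this literature are only self-consistent when
"normal" is read as the positive class, so reports never leave the
convention implicit.
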