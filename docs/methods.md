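# Methods

## Problem and approach

Wearable devices record photoplethysmography (PPG) far more comfortably than
electrocardiography (ECG), but clinical interpretation — rhythm analysis, AF
screening, morphology — is defined on the ECG. This package implements a
translation model that maps a normalized PPG window to a same-length ECG
window, trained adversarially with a Wasserstein objective, and the full
experimental apparatus around it: paired-signal simulation, preprocessing,
self-supervised critic pre-training, evaluation metrics, two-sample
distribution tests and an AF-detection downstream harness.

All neural-network machinery (a reverse-mode autodiff engine with
second-order support, convolutional/attention/recurrent layers, Adam) is
implemented in-package on numpy in float64. The gradient penalty needs
gradients of a function of the critic's *input gradient* with respect to the
critic's *parameters*; every vector–Jacobian product in the engine is itself
built from differentiable primitives, so double backprop falls out of the
design rather than being special-cased.

## Models

**Generator** — a 1-D UNet. The encoder applies L stride-2 convolutions
(default channel schedule 16, 16, 8, 8), halving the sequence length each
layer. At the bottleneck the 8-channel map is expanded to 16 channels by a
1×1 convolution, each time step becomes a token (projected to d = 64),
learned positional embeddings are added, and a pre-norm Transformer with
causal self-attention and GELU MLPs (2 layers, 2 heads by default) models
long-range structure. The decoder mirrors the encoder with transposed
convolutions; the encoder map at depth i is concatenated with the decoder
input at depth L−i+1 (standard UNet pairing). The final activation is Tanh,
matching the (−1, 1) range of normalized windows. Inputs whose length is not
divisible by 2^L are zero-padded and the output cropped.

**Critic** — a BERT-style Transformer discriminator. A three-layer stride-1
conv encoder (kernels 65/33/17, channels 64/128/256, ReLU, layer norm on the
first layer and the encoder output) is average-pooled into s = 64 tokens
(the token count is not a printed constant; pooling keeps the architecture
length-agnostic), projected to d_model = 256, prefixed with a CLS token,
summed with learned positional embeddings, normalized and passed through a
2-layer, 2-head Transformer with FFN width 512. Heads on the CLS
representation:

- *critic*: FC 256→512→256→1 with no output squashing (Wasserstein score);
  the 512-wide activation is the embedding used for distribution analysis;
- *pretext*: two shared FC-128 + ReLU layers and six binary logits, one per
  transformation task;
- *masked-point*: FC 256→128→1 per token — constructed for architectural
  completeness, unused by default since no masking task is part of the
  training procedure.

**AF classifiers** — a bidirectional two-layer LSTM (128 hidden units per
direction, dropout 0.5, two FC-256 + ReLU layers, sigmoid output) and a
CNN+LSTM variant that prepends two conv(kernel 4)+maxpool(2,2) stages,
quartering the temporal length. Hidden sizes are configurable; desk-scale
tests use reduced widths.

## Losses

With critic D, generator G, real ECG e, input PPG p:

    L_G  = −E[D(G(p))]
    L_GP = λ · E[(‖∇_x̂ D(x̂)‖₂ − 1)²],  x̂ = ε e + (1−ε) G(p),  ε ~ U(0,1)
    L_D  = −E[D(e)] + E[D(G(p))] + L_GP

λ defaults to 30 (the best value of the searched grid {4, 6, 30, 50}). An
optional supervised reconstruction term (weight 0 by default) is available
for warm-starting; the pure objective is the adversarial one.

## Synthetic data

Each subject is a parameter vector: mean heart rate (drawn U(55, 95) bpm),
RR-interval SD (U(0.02, 0.07) s), P/R/T amplitudes (U(0.1,0.2) /
U(0.8,1.4) / U(0.2,0.4) mV), pulse-arrival lag (U(0.15, 0.35) s), artifact
level and a seed. These resting-range defaults emulate the structure of
consumer-wearable recordings (chest-strap ECG at 130 Hz, wrist PPG at
64 Hz).

- **ECG**: per beat, five Gaussian bumps (P, Q, R, S, T) at fixed phase
  offsets, compressed for short cycles so consecutive beats never overlap.
  R times are snapped to the sampling grid, making the discrete argmax
  coincide exactly with the reported ground-truth peak — this is what lets
  peak-detector tests demand recall = precision = 1 at ±1 sample. The
  QRS-free component (P and T bumps only) is returned alongside, providing
  an exact oracle for the QRS-excision analysis.
- **RR intervals**: i.i.d. truncated normal. Real HRV is autocorrelated;
  i.i.d. draws satisfy the mean/SD statistics the generator is specified by
  and keep the oracle for RR-SD trivial. Autocorrelated HRV would not change
  any downstream contract.
- **PPG**: per beat an asymmetric Gaussian pulse (rise σ 0.07 s, fall σ
  0.16 s) peaking exactly at R + lag, plus a dicrotic bump as a scaled copy
  delayed 0.30 s, on a small positive baseline.
- **Motion artifacts**: 0.1–1 Hz band-passed drift, Poisson-arriving
  transient spikes, and slow (0.05–0.2 Hz) multiplicative amplitude
  modulation, all scaled linearly by `level` relative to the signal SD.
  Level 0 is the bit-exact identity. The severity scale is a knob, not a
  calibration to any real dataset.

What the generator does **not** emulate: respiratory coupling, baseline
morphology drift, beat-to-beat morphology variability, sensor quantisation,
skin-tone/wavelength effects, real artifact statistics. Passing tests
therefore demonstrate the correctness of the machinery (losses, gradients,
metrics, pipelines), not clinical performance on real recordings.

## Preprocessing

Order: align → resample → filter → median despike → segment → normalize.

- **Alignment**: one global pulse-arrival lag per record, found by scanning
  cross-correlation of Gaussian-smeared peak trains over lags in [0, 0.6] s
  (2 ms steps); the PPG is shifted earlier and edge-padded. Systolic peaks
  for lag estimation are detected on a 0.5–15 Hz band because the 8 Hz
  analysis low-pass visibly delays the asymmetric systolic peak (~10 ms,
  more than one 130 Hz sample).
- **Resampling**: cubic spline onto a uniform 130 Hz grid.
- **Filtering**: ECG — zero-phase windowed-sinc FIR, 0.5–45 Hz, symmetric
  'same' convolution with reflect padding (taps ≈ 4·fs/low-edge, capped by
  the signal length); PPG — forward–backward 4th-order Butterworth,
  0.5–8 Hz. Zero phase preserves R-peak timing, on which MAE-HR depends.
- **Median despike**: running median, kernel 5 (~38 ms at 130 Hz) — wide
  enough for single-sample spikes, narrower than a QRS complex.
- **Segmentation**: windows from {4, 8, 16, 32, 64, 96, 128, 160} s with
  20 % overlap; hop = round(w·(1−overlap)); trailing partial windows are
  dropped; count = floor((N−w)/hop)+1.
- **Normalization**: per-subject min–max onto (−1, 1), fitted on the
  training portion of each record (default 80 %) and reused on the rest to
  avoid leakage under leave-one-subject-out validation. Out-of-range values
  at application time are clipped with a counted warning. The mapping is
  affine and inverted exactly before computing millivolt-scale metrics.

## Pretext tasks

Six pseudo-labeled transformations per ECG window, parameters drawn
uniformly: additive Gaussian noise at SNR α ∈ [2, 45] dB, scaling
b ∈ [0.1, 10], temporal inversion, permutation of m ∈ [2, 40] contiguous
parts (identity shuffles resampled away), negation, and time warping
(m segments, a random half stretched by k ∈ [1.05, 4], the rest compressed
by 1/k, clipped or zero-padded back to length).

The noise-power rule E_Navg = 10^((E_Eavg − α)/10) is read with E_Eavg in dB
(10·log₁₀ of mean squared amplitude) and powers in linear units — the only
dimensionally coherent convention; achieved SNR is within ±0.5 dB of target
averaged over 100 four-second windows.

Multi-task pre-training drives six binary heads (original = all heads
negative) with sigmoid cross-entropy. Because each task is positive for
exactly 1/7 of the examples, the loss weights positives by the inverse class
ratio (capped at 10); without this the heads collapse to constant
predictors at small sample sizes. Per-task validation accuracy is reported
by k-fold cross-validation (10-fold by default, fewer at desk scale),
followed by a final fit on all examples. The Transformer blocks of the
pre-trained critic are frozen during adversarial fine-tuning; the conv
encoder and heads stay trainable.

## Training protocol

Alternating optimisation: 5 critic steps (Eq. L_D) per generator step
(L_G), Adam with betas (0.5, 0.9). The printed grid also lists decay values
{1, 3}, which are not valid Adam rates; config validation rejects betas
outside (0, 1). Early stopping (patience 10) monitors validation RMSE
between generated and reference ECG. A divergence guard aborts when the
critic loss magnitude exceeds a configurable bound for 3 consecutive epochs.
Leave-one-subject-out folds hold out one subject entirely; 10 % of training
segments (training subjects only) form the validation split. The full
hyper-parameter grid (λ × learning rate × batch = 24 configurations) is
exposed through an expander with a `--budget` cap.

Desk-scale study sizes (used by the test-suite and the acceptance script,
chosen so the whole battery runs on one CPU): reduced generator
(depth 2, bottleneck d = 16) and critic (channels 8/16/32, d_model = 32,
16 tokens); 2–10 subjects × 60–120 s; 4–8 s windows; GAN runs of 8 epochs ×
5 steps × batch 16. These sizes demonstrate the optimisation properties
(gradient-norm drift toward 1 under λ = 30, loss-spread blow-up at λ = 0,
memorisation capacity on 5 pairs) — not generative quality, which requires
the full-scale configuration.

## Evaluation

Metrics are computed per window after exact denormalization to mV:

- **RMSE** and **Pearson ρ** by their textbook formulas.
- **Discrete Fréchet distance** between the curves (t, y), (t, ŷ) via the
  standard coupling dynamic program (numba-accelerated with a pure-Python
  fallback). The printed min–max formulation in the source literature is not
  a well-defined coupling metric; its prose description matches the standard
  discrete Fréchet distance, which is what is implemented and verified
  against exhaustive coupling enumeration for short curves.
- **MAE-HR**: per segment, HR = 60 / mean RR from detected peaks; segments
  with fewer than two peaks in either train are excluded and counted. R
  peaks come from a Pan–Tompkins-style detector (5–15 Hz band-pass,
  derivative, squaring, 150 ms moving-window integration, adaptive
  signal/noise thresholds, 200 ms refractory period) with detections
  refined to the raw-signal extremum (|x − median|, hence polarity-robust).
  PPG systolic peaks use a clipped slope-sum function (128 ms window) with
  adaptive thresholding, event windows and a 250 ms minimum spacing.

## Distribution analysis

512-dimensional critic embeddings (the penultimate scoring-head activation)
of real and generated windows are compared with an unbiased Gaussian-kernel
MMD² (median-heuristic bandwidth; for equal sample sizes the matched-pair
estimator excludes the k(x_i, y_i) diagonal so identical multisets score
exactly zero) and the energy distance (plug-in V-statistic, zero for
identical samples). Permutation tests pool both samples, re-split
size-preservingly, and report p = (1 + #{perm ≥ observed})/(1 + n_perm)
(default n_perm = 1000) plus a permutation-resampling SD. t-SNE projection
(perplexity 50, learning rate 600) is provided for visualisation only.

## AF harness and baseline analysis

Synthetic AF-like records combine high RR variability (SD 0.12–0.20 s),
absent P waves and 4–9 Hz fibrillatory baseline activity; sinus records are
ordinary cohort draws. The data-mixing protocol trains classifiers on
real/generated mixtures in 25 % increments at constant total size, with
subject-disjoint train/test splits, and reports
accuracy/precision/recall/F1 with the confusion matrix (probability
threshold 0.5, no calibration). At desk scale the CNN+LSTM is the
practical choice — its conv/pool front end quarters the recurrence length,
making it an order of magnitude faster per epoch than the Bid-LSTM and
noticeably more stable on small cohorts.

Baseline isolation removes ±60 ms around each R peak (configurable; covers
QRS ≤ 120 ms) and bridges linearly. Band power uses a Welch periodogram
(8 s Hann windows, 50 % overlap; 0.125 Hz resolution — adequate for the
3–9 Hz band, marginal at the 0.05 Hz edge, where ≥ 20 s windows can be
configured) integrated by the trapezoid rule over 0.05–9, 0.05–1 and
3–9 Hz.

## Numerical and design notes

- float64 everywhere; loss identities hold to 1e−6, affine normalization
  round-trips to 1e−9, two-sample statistics match brute-force loops to
  1e−10.
- Softmax subtracts a detached max (shift-invariance makes the gradient
  exact); max-pool routes sub-gradients to the first argmax; dropout masks
  come from per-layer generators seeded at construction, so training
  trajectories are bit-reproducible given the config seed.
- After a first-order backward pass the traversed graph is released
  explicitly (vjp closures form reference cycles a node's closure captures),
  keeping long training loops at constant memory; graphs built with
  ``create_graph=True`` for the gradient penalty are kept until the outer
  parameter backward frees them.
- One global seed fans out to per-stage seeds via `SeedSequence.spawn` in a
  fixed stage order; manifests record content digests (npz archives hashed
  member-wise so zip metadata cannot break reproducibility).
- Degenerate inputs fail loudly: zero-variance windows for ρ, all-zero
  signals for SNR, flat traces for peak detection, constant channels for
  min–max fitting.

## Known limitations

- Synthetic morphology is Gaussian-bump stylised; no claim of physiological
  fidelity of generated waveforms transfers to real data.
- The critic token count, generator bottleneck width and several training
  constants are configuration defaults, not reproductions of unpublished
  values.
- The masked-point head is architecturally present but untrained by
  default.
- Desk-scale GAN runs show the optimisation signatures of the method; they
  do not reach the reconstruction quality regime of full-scale training.
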