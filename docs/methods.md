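# Methods

This note records the scientific and numerical choices behind `awcop`: the
model, the synthetic study conditions, the pulse analysis conventions, and
the places where the design was genuinely open.

## Prediction task and model

The endpoint is binary: coronary stenosis ≥ 75% (label 1) vs < 75%
(label 0), the usual threshold for intervention. Four modality encoders
produce 128-dimensional embeddings (conv + residual + attention stems for
tongue and face images, an LSTM over the 6-s radial pulse segment, a dense
layer over 15 screened lab features); a decision layer fuses them and a
dense head emits two logits.

**Adaptive fusion.** One learnable raw scalar per modality, softmax-
normalized, scales its embedding before concatenation (4 × 128 = 512). The
regularizer R = Σ raw² is added to the loss with weight `reg_lambda`
(default 1e-4), pulling raw weights toward zero, i.e. normalized weights
toward uniform: modalities must earn deviation from 1/4. Raw weights start
at zero, so at initialization the adaptive model equals the plain-concat
model up to a 1/4 head rescaling — a property the tests check exactly.
A weighted *summation* of four 128-vectors could not produce the 512-wide
fused layer the architecture table specifies; weight-scaled concatenation
is the only dimensionally consistent reading, and is what we implement.

**Other decision layers** (for the fusion comparison): plain concatenation;
elementwise max, mean and sum; and a single scaled-dot-product attention
layer treating the four embeddings as tokens, averaged after mixing. Heads
are sized to the fused width (512 or 128).

**Self-attention over a single 128-vector** is undefined as stated;
branch attention reshapes the embedding into 8 tokens × 16 dims with
learned Q/K/V (one head) and flattens back. No positional encodings are
used anywhere, since none are described for this architecture.

**Training.** Adam, default learning rate 0.001 (a sweep over
{0.001, 0.005, 0.01, 0.05} is built in; 0.05 destabilizes training, which
the property tests reproduce). Cross-entropy with inverse-frequency class
weights; default 30 epochs, batch 16, early stopping on internal-split AUC
with patience 8, keeping the most recent best state (later states with
equal AUC are better calibrated at the 0.5 accuracy threshold). ACC uses a
fixed 0.5 threshold; F1 and recall are reported for the positive class.
All randomness flows through explicit integer seeds; repeated runs are
bit-identical, including written files.

**Numpy compute core.** The network runs on a small reverse-mode autograd
written for this package (`awcop.nn`): coarse-grained ops (im2col + GEMM
convolution, fused-BPTT LSTM, batch-norm, pooling, attention from dense
primitives) keep graphs small enough for CPU training in float64. Every op
is verified against central finite differences in the test suite.

## Pulse analysis

Preprocessing is moving-average smoothing (default window 3 samples) and
baseline-drift removal by subtracting a 2nd-order zero-phase Butterworth
low-pass trend (default cutoff 0.5 Hz). From each 30-s, 50-Hz recording the
6-s window whose systolic peak heights have minimal variance is selected
(ties to the earliest onset; peaks found with a 0.4-s minimum distance —
bounding heart rate at 150 bpm — and a prominence threshold set from the
10–90 percentile range so isolated artifacts cannot mask regular beats).
Cycles are delimited at diastolic minima between successive systolic peaks.

Per cycle, with baseline = onset value (robust to residual drift):
h1/t1 = main-wave height/time (parabolic sub-sample interpolation — at
50 Hz the systolic upstroke spans ~7 samples, and grid-resolution timing
would dominate the error budget); h4/t4 = deepest post-peak local minimum
(dicrotic notch); h5 = first local maximum after the notch (dicrotic wave);
h3 = local maximum between main peak and notch (tidal wave), falling back
to the steepest-negative-curvature point of the descending limb when no
distinct maximum exists (flagged); t = cycle length, t5 = t − t4. The
"top third / top fifth of the primary wave" widths are measured as the
contiguous time above (2/3)·h1 and (4/5)·h1 over baseline, with linearly
interpolated crossings, which guarantees w2 ≤ w1. Cycles without a
detectable notch are flagged degenerate and their notch-dependent ratios
nan-averaged out of the per-patient table. The per-patient table has the
15 canonical columns (h1, h3, h4, h5, t, t1, t4, t5, h3/h1, h1/t1, h4/h1,
t1/t, t4/t5, w1/t, w2/t).

## Synthetic study conditions

The generator defines the conditions every test runs under.

* **Tongue**: elliptical tongue with a central coating patch; class 1
  shifts the coating hue by 40° (per-patient jitter SD 3°); pixel noise
  SD 8/255.
* **Face**: elliptical face; class 1 brightens forehead, nose and cheek
  masks by +30 (of 255); global exposure jitter SD 4.
* **Pulse**: concatenated cycles of three Gaussian bumps — percussion
  (amplitude h1 ≈ 1 at 0.18 T, σ 0.03 s), tidal (h3 = r·h1 at 0.34 T,
  σ 0.045 s), dicrotic (0.25·h1 at 0.58 T, σ 0.04 s) — on a raised-cosine
  diastolic base (8% of h1); a notch emerges between tidal and dicrotic
  waves. Class 1 shifts the mean tidal ratio r from 0.45 by +0.15
  (patient SD 0.05, cycle SD 0.02). Periods are drawn per patient
  (0.85 ± 0.06 s, clipped to [0.7, 1.1]) and rounded to whole samples so
  cycle onsets fall exactly on the grid; bump placement keeps the onset
  sample the strict waveform minimum, which is what makes exact fiducial
  recovery testable. Baseline drift 0.1 at 0.15 Hz plus white noise
  SD 0.02. Realized landmark values are computed from the continuous
  noiseless model on a dense grid and stored as ground truth. An optional
  `pulse_alternans` channel alternates beat amplitudes (pulsus alternans):
  cycle-averaged parameters are blind to it, so it isolates what only a
  sequence model can see.
* **Labs**: 50 named columns; fibrinogen-, D-dimer-, FDP- and
  myoglobin-like markers shifted by 0.8/0.6/0.5/0.8 SD in class 1; binary
  hypertension-like (0.45 → 0.60) and diabetes-like (0.30 → 0.45) risk
  factors; the rest standard normal. Splits are stratified 70/15/15
  (train/internal/external).

What the generator does **not** emulate: photorealistic anatomy, real
marginal lab distributions, device-specific pulse units (ratios are
unit-free), inter-device variability, or label noise. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
controlled conditions — not clinical performance, which would require the
(private) patient data.

## Interpretability

Grad-CAM uses the output of the 4th residual block: channel weights are
spatially averaged gradients, the map is the rectified weighted sum,
bilinearly upsampled and min-max normalized (flat maps normalize to zero).
With a two-logit head, evidence shared by both classes cancels only in the
logit *margin*, and empirically the single-logit map anti-correlates with
an occlusion probe while the margin map tracks it (rank correlation ≈ 0.8
on a coating-signal model); the margin is therefore the default target,
with the raw class logit available via `contrast=False`. Maps explain the
predicted class unless a class is requested.

Pulse saliency is the per-timestep magnitude of the input gradient
(gradient × input optional), with the top 20% of timesteps marked
(ceil count — 60 of 300; ties broken toward earlier indices). A known
limitation: with a final-hidden-state LSTM readout, input gradients decay
going back in time, so marked points concentrate on the most recent one to
two cardiac cycles rather than distributing across the strip; the tests
document this recency rather than pretending wave-phase enrichment.

## Screening and baselines

Numeric labs: two-sided Mann–Whitney U (normal approximation with tie
correction), median (Q1, Q3) summaries. Binary labs: 2×2 chi-square
without continuity correction (degenerate/constant features flagged, not
fatal). Raw p-values are primary; a Benjamini–Hochberg column is an
optional, labelled extension. Feature selection is a 500-tree random
forest's impurity importance, top 15, fit on the training split only.
Baselines (logistic regression, random forest, SVM-RBF, KNN-5, XGBoost
with 100 rounds at depth 3) consume the 15 pulse parameters, per-region
color statistics (mean/SD per channel in RGB, HSV and L*a*b* for the whole
tongue, the coating patch and three facial regions — standing in for
proprietary instrument parameters), and the 15 screened labs, standardized
with training-split statistics; SVM and other margin-only models are
scored through a sigmoid of the decision margin so the 0.5 threshold sits
at the decision boundary.

## Problem sizes

Everything runs on one CPU core. Default images are 64×64 (even dimensions
are required by the 2×2 pool); the test suite and acceptance script use
12–32 px images and cohorts of 24–300 patients, sizes at which every
planted effect is still comfortably detectable: the data-ablation ordering
uses n = 300 over 5 seeds at 4 epochs; the waveform-dynamics comparison
uses n = 150 at 20 epochs (the recurrent branch needs full convergence
before representation comparisons are meaningful); the learning-rate
contrast uses n = 60 at 5 epochs. Determinism is checked by running the
entire staged pipeline twice on a 40-patient cohort and comparing SHA-256
manifests of every output byte.

## Known limitations

* Synthetic cohorts only; no claim transfers to clinical data.
* Grad-CAM at 8×8–16×16 feature-map resolution is blurry; localization
  checks need ≥ 32 px inputs.
* Pulse saliency inherits the recency bias of final-state LSTM readouts.
* The minimum-variance segment selector assumes at least two clean beats
  in some 6-s window; recordings failing that raise rather than guess.
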