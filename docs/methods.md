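# Methods

## Problem and model

Non-invasive fetal ECG is recorded from electrodes on the maternal abdomen;
each channel is a mixture of the maternal ECG (dominant, ~60–90 bpm, tens of
microvolts), the fetal ECG (much smaller, ~110–160 bpm) and noise.  The task
is to decide, for every 100 ms frame of a one-second 4-channel window
sampled at 1000 Hz, whether it contains a fetal QRS complex.

The detector is a fully convolutional residual network followed by a small
recurrent head:

* **Trunk** — three residual blocks of three 1-D convolutions each (kernel
  lengths 8, 5, 3; 64/128/128 filters per block), every convolution followed
  by batch normalization and ReLU, with a 1×1 convolution (plus batch
  normalization) shortcut bridging each block; the shortcut is added to the
  third convolution's BN output before the block's final ReLU.  Stride is 1
  everywhere and padding preserves length, so the trunk maps 4×1000 to
  128×1000.
* **Octave convolutions** — every trunk convolution is a 1-D octave
  convolution: a fraction α of its channels live at half temporal
  resolution (the "low-frequency" group), and four weight paths
  (H→H, H→L, L→H, L→L) exchange information between the groups, with
  average-pooling (k=2, stride 2) down and nearest-neighbour repetition up.
  The first convolution has α_in = 0, the last α_out = 0, so the trunk
  consumes and produces ordinary full-rate maps.  Splitting a kernel into
  the four groups conserves the parameter count exactly, while per-layer
  multiply-accumulates shrink by the closed-form factor 1 − α(1 − α/2) and
  feature storage by 1 − α/2.
* **Head** — the 128×1000 trunk output is cut into ten 100-sample frames,
  each global-average pooled to a 128-vector; a bidirectional GRU with
  hidden size 32 integrates the ten-frame sequence (reset/update gates,
  with the reset gate applied inside the recurrent candidate term,
  ĥ = tanh(Wx + U(r⊙h))); a shared 64→2 affine softmax scores each frame.

## Training

Class-weighted binary cross entropy over the ten frame decisions, with the
positive-class term up-weighted by β = 2 to counter the scarcity of
fQRS-containing frames; probabilities are clamped to [1e−7, 1 − 1e−7].
Optimization is Adam (learning rate 1e−3, β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
constant schedule), Xavier/Glorot initialization, dropout 0.4 applied to
the pooled frame sequence before the GRU and to the GRU output before the
classifier, batch size 64, and the checkpoint with the highest validation
frame-F1 is kept.  Training windows are standardized per window and channel
(zero mean, unit variance) by default.  Evaluation is frame-level
precision/recall/F1 with predicted class = argmax of the probability pair;
zero denominators yield metric 0 with a `degenerate` flag.

## Compute core

No deep-learning framework is used: the package ships a small reverse-mode
autodiff engine on numpy (`octaveqrs.nn`) with hand-written
vector–Jacobian products for each primitive.  Activations are laid out
channels-last, and the stride-1 convolution is computed as one large GEMM
per kernel tap on the zero-padded input, which keeps the hot path inside
BLAS on a single CPU.  Every primitive's gradient is verified against
central finite differences in the test suite, as is the composed network.
Inference runs with graph recording disabled; backward passes release
graph edges as they are consumed to bound memory.

## Cost model

Costs count one FLOP per multiply-accumulate; bias additions, batch
normalization, ReLU, pooling and resampling are excluded.  This convention
makes the vanilla (α = 0) trunk — nine convolutions plus three 1×1 shortcut
convolutions at length 1000 — cost 0.518e9 MACs ≈ 0.52 GFLOPs, and the
recurrent head 2·10·3·(128·32 + 32·32) + 10·64·2 ≈ 3e−4 GFLOPs.  Shortcut
convolutions are counted (and built) in all three blocks, including the
third where channel counts already match; an identity shortcut there would
give 0.50 GFLOPs instead.  Because the boundary layers use (0, α) and
(α, 0) ratios, the whole-trunk octave cost does not scale exactly by the
per-layer closed form: at α = 0.25 the trunk computes 0.41 GFLOPs (ratio
0.79 instead of 0.78).  Parameters total 553,282 ≈ 0.55 million at every α
(conservation is asserted), counting conv weights and biases, batch-norm
scale/shift (including shortcut BN), both GRU directions (packed input and
recurrent matrices plus one bias per gate) and the shared classifier.

## Grad-CAM

For a chosen frame and class, the gradient of the pre-softmax score with
respect to the final 128×1000 feature map is averaged over the 100 samples
of that frame (the region whose pooled feature feeds the score; a
whole-window averaging mode is available), giving one weight per channel;
the attention trace is the ReLU of the weighted channel sum.  The final
map is already full-resolution, so no upsampling is needed, and the trace
aligns sample-for-sample with the input.  One forward and one backward
pass per map.

## Synthetic data generator

The generator emulates exactly the structure the detector assumes: a
maternal beat train (uniform heart rate in 60–90 bpm, RR jitter CV 0.02
truncated at ±20%), a fetal train (110–160 bpm, same jitter), each beat
rendered as five Gaussian bumps (P, Q, R, S, T) with fixed offsets and
widths (fetal template time-compressed by 0.6), per-channel mixing gains
drawn from [0.5, 1], fetal R amplitude a configurable fraction of the
maternal 25 μV (default 0.2), and additive Gaussian sensor noise (default
1 μV).  Ground-truth fetal R-peak indices are exact by construction.
Motion artifacts are modelled separately as sub-1 Hz random-phase sinusoids
plus sparse smoothed steps added to [−1, 1]-normalized signals; graded
Gaussian noise rescales a max-|·|-4 μV Gaussian field by the level factor.

What the generator does **not** model: volume conduction and electrode
geometry, fetal movement and vernix attenuation, maternal ectopy, coupled
rhythms, and real motion noise statistics.  Passing the synthetic training
check therefore shows that the pipeline — windowing, octave trunk,
recurrent head, weighted loss, selection by validation F1 — learns to find
small sharp deflections under a dominant interfering rhythm; it does not
certify clinical-grade scores on real abdominal recordings, which require
the PhysioNet 2013 set A and full-length training.

## Problem sizes used by the automated checks

The acceptance training run uses 13 synthetic training recordings of 60 s
(780 non-overlapping windows) and 3 validation recordings (180 windows),
fetal amplitude ratio 0.3, α = 0.25, 4 epochs with batch 32, one fixed
seed; the pass bound is validation frame-F1 ≥ 0.8, with the all-negative
baseline at F1 = 0.  These sizes were chosen as the smallest at which
training is comfortably above the bound; more data and epochs only help.
The Grad-CAM localization check reuses that fitted model and requires the
attention maximum within 50 ms of a true fetal R peak for ≥ 70% of sampled
correctly-detected frames.

## Numerical choices and edge cases

* Even kernels pad (k/2 − 1, k/2); convolution is cross-correlation.
* Channel split: c_low = round(αc) — exact for all shipped configurations.
* Octave bias is added once per output branch after the two paths sum.
* Nearest upsampling uses out[t] = in[t ∕ 2] (repetition).
* Batch-norm momentum 0.1, ε 1e−5; running variance uses the unbiased
  correction.
* The weighted loss is computed on the softmax logit difference
  (p = σ(z₁ − z₀)) for numerical stability.
* Windows shorter than 1 s are dropped (with a warning for whole-recording
  inputs shorter than one window); frame intervals are half-open, 0-based.
* Degenerate inputs raise: odd lengths where the octave split needs even,
  constant channels under [−1, 1] normalization, mismatched α between a
  factorized map and a layer.

## Design choices where the design was open

* Frame-level evaluation is primary (matching the model's output
  granularity); a 50 ms peak-tolerance mode is the natural secondary for
  real annotated data and is recorded as window metadata.
* Model selection uses validation F1.
* The GRU carries one bias per gate on the input transform.
* Bidirectional states merge by concatenation (64 = 2×32).
* Dropout sits at the two head sites listed above; the trunk is undropped.
* Training stride is 1000 (non-overlapping); overlap is exposed as a
  windowing parameter for augmentation.

## Known limitations

Real WFDB support covers format-16 .hea/.dat records with plain-text
annotation lists; binary WFDB annotation files are not parsed.  The
cost model excludes elementwise work and memory traffic, so it ranks
configurations rather than predicting wall-clock time.  Training on a
single CPU is practical at the scaled-down sizes above but not at
clinical scale.
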