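# octaveqrs

Fetal QRS detection from 4-channel non-invasive abdominal ECG with a 1-D
octave-convolution residual network — plus the analytic compute/memory cost
model for octave convolutions, a 1-D Grad-CAM explainer, and a synthetic
fetal/maternal ECG simulator so the whole pipeline builds and tests without
any clinical data.

## Who this is for

Researchers and engineers working on non-invasive fetal monitoring who need
an end-to-end fQRS detector that runs cheaply enough for wearable-class
hardware, and who want to reason quantitatively about the compute/accuracy
trade-off of multi-frequency (octave) feature maps in 1-D signals.

## The model

A one-second 4×1000 window (1000 Hz, μV) is classified into ten 100 ms
frame decisions ("contains a fetal QRS complex" or not):

* **Octave-convolution ResNet trunk** — three residual blocks of three
  convolutions (kernel lengths 8/5/3; 64/128/128 filters), each convolution
  an octave convolution: a fraction α of channels is stored at half
  temporal resolution, and four weight paths W^{H→H}, W^{H→L}, W^{L→H},
  W^{L→L} exchange information between the full-rate and half-rate groups,

      Y^H = f(X^H; W^{H→H}) + upsample(f(X^L; W^{L→H}), 2)
      Y^L = f(X^L; W^{L→L}) + f(pool(X^H, 2); W^{H→L})

  Per layer this costs 1 − α(1 − α/2) of the vanilla multiply-accumulates
  and 1 − α/2 of the feature storage, at an identical parameter count.
* **Recurrent head** — the 128×1000 trunk output is split into ten frames,
  global-average pooled, passed through a bidirectional GRU (hidden 32) and
  a shared softmax, one probability pair per frame.
* **Training** — weighted binary cross entropy (positive frames up-weighted
  by β = 2), Adam (lr 10⁻³), Glorot initialization, dropout 0.4, best
  checkpoint by validation F1.
* **Explanation** — 1-D Grad-CAM: channel weights α_k^c = mean_t ∂y^c/∂A_k,t
  over the target frame, attention = ReLU(Σ_k α_k^c A^k), aligned
  sample-for-sample with the input window.

Everything, including backpropagation, runs on numpy (a small reverse-mode
autodiff engine ships in `octaveqrs.nn`); no GPU or deep-learning framework
is required.

## Worked example

Simulate abdominal recordings, fit the α = 0.25 detector, and inspect it:

```python
import numpy as np
from octaveqrs import (FetalQRSDetector, NetworkConfig, SynthConfig,
                       TrainConfig, generate_recording)

train_recs = [generate_recording(SynthConfig(duration=60.0,
                                             fetal_amplitude_ratio=0.3, seed=s))
              for s in range(8)]
val_recs = [generate_recording(SynthConfig(duration=60.0,
                                           fetal_amplitude_ratio=0.3, seed=s))
            for s in range(100, 102)]

model = FetalQRSDetector.from_recordings(
    train_recs, val_recs,
    config=NetworkConfig(alpha=0.25),
    train_config=TrainConfig(epochs=3, batch_size=32, seed=0),
)
results = model.fit(verbose=True)
print(results.summary())

window = model.val_data[4]
preds = results.predict(window.samples)
print("frame labels:   ", window.frame_labels.tolist())
print("P(fQRS present):", [round(float(p), 2) for p in preds.positive])
```

Output:

```
epoch   0  loss 5.6379  val F1 0.6533  (38.1s)
epoch   1  loss 2.2714  val F1 0.9419  (38.7s)
epoch   2  loss 1.3782  val F1 0.9144  (38.3s)
Fetal QRS detector fit
====================================================
octave ratio alpha          0.25
parameters                  0.55 M
trunk compute               0.41 GFLOPs/window
recurrent head compute      0.0003 GFLOPs/window
epochs run                  3
best epoch (val F1)         1
validation F1               0.942
validation precision        0.972
validation recall           0.914
====================================================
frame labels:    [0, 0, 1, 0, 0, 0, 1, 0, 0, 0]
P(fQRS present): [0.02, 0.01, 0.22, 0.01, 0.0, 0.01, 0.99, 0.02, 0.01, 0.29]
```

The fit keeps epoch 1 (highest validation F1 = 0.942).  On the shown
window the detector is confident about the fetal beat in frame 6 and
hesitant about the one in frame 2 — a beat that coincides with a maternal
QRS complex, the hard case for abdominal extraction.  `results.explain(
window.samples, frame=6)` returns the Grad-CAM attention trace showing
which samples drove that decision; `octaveqrs explain` writes the same
trace as CSV (optionally with a plot) from the command line.

The CLI mirrors the library: `octaveqrs simulate | train | eval | cost |
explain` (see `octaveqrs --help`); real recordings are read from WFDB
format-16 `.hea`/`.dat` files or a 4-column CSV, with fetal R-peak
annotations as plain-text sample-index lists.

## Cost model

```bash
octaveqrs cost --alpha 0.25
```

reports per-layer and total multiply-accumulates (0.41 GFLOPs/window at
α = 0.25 vs 0.52 at α = 0, of which the recurrent head is only ≈3×10⁻⁴),
feature-memory units, the closed-form per-layer ratios, and the parameter
count (0.55 M, identical for every α).

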