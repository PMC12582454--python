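# rntnet

Hybrid residual/transformer classification of colorectal images — a
reusable implementation of **RNTNet** (Residual Next Transformer Network)
with its full evaluation harness, runnable end-to-end on CPU with synthetic
data.

Colorectal cancer screening produces two kinds of images that need
multi-class classification: endoscopic frames (anatomical landmarks,
pathological findings, polyp-removal stages) and stained histology patches
(tumour, stroma, lymphocytes, …). Plain CNNs capture local texture but
miss global spatial correlations; plain vision transformers (ViT) capture
global context at quadratic cost and miss fine local structure. RNTNet
combines both:

* a **ResNeXt-style backbone** — four stages of bottleneck blocks with
  grouped 3×3 convolutions (cardinality 32) and skip connections,
  `X' = ReLU(X₃ + Skp(X))` — extracts a spatial feature map at stride 32;
* a **mixed-attention ViT encoder** runs three branches in parallel on the
  tokenized map and fuses them per token,
  `Z_F = Proj(Concat(Z_O, Z_G, X_out))`:
  * *overlapping block attention* (OBA): softmax attention inside B×B
    token blocks at stride s < B, overlaps merged by a convex weighted
    average — local context;
  * *grid attention* (GA): attention within G×G interleaved (dilated)
    token groups after stride-2 pooling — global context;
  * a standard transformer branch
    `X_out = Norm(X + Atten(Q,K,V) + FFN(X))`;
* a **dense head** (256 units, ReLU, 20 % dropout, softmax) trained with
  categorical cross-entropy `L = −Σᵢ pᵢ log p̂ᵢ`.

The attention cost of the mixed block scales as O(M²D²) in the token count
M at embedding dimension D, versus the O(M⁴D)-type growth of dense
all-pairs attention in the feature-map side.

The package ships the full evaluation harness: confusion-matrix metrics
(accuracy, macro precision/recall/F1, Cohen's kappa), one-vs-rest ROC/AUC,
stratified 80/20 splits and 5-fold cross-validation, the patch-size sweep,
a paired t-test for per-class indicators, Grad-CAM heatmaps, analytic
parameter/FLOP accounting, and a deterministic synthetic texture-dataset
generator so every stage is testable without downloads. The network runs
on a compact NumPy autodiff core included in the package — no GPU or deep
learning framework required.

## Worked example

Train the width-reduced preset on the synthetic 8-class texture fixture
(320 images) and evaluate — a couple of minutes on one CPU core:

```python
import numpy as np
from rntnet import (RNTNetClassifier, SynthSpec, generate_arrays,
                    confusion_matrix, classification_metrics)

X, y = generate_arrays(SynthSpec(n_classes=8, per_class=40, seed=7))
est = RNTNetClassifier(preset="reduced", epochs=30, batch_size=16,
                       learning_rate=1e-3, val_fraction=0.2,
                       early_stop_acc=0.9, random_state=7)
est.fit(X, y)

probs = est.predict_proba(X)
m = classification_metrics(confusion_matrix(y, probs.argmax(axis=1), 8))
print(f"epochs run: {len(est.history_['val_acc'])}")
print(f"validation accuracy: {est.history_['val_acc'][-1]:.3f}")
print(f"training-set accuracy: {m.accuracy:.3f}  kappa: {m.kappa:.3f}")
```

```
epochs run: 2
validation accuracy: 1.000
training-set accuracy: 1.000  kappa: 1.000
```

The fixture's eight texture classes (oriented gratings + band-passed noise
+ blob fields) are separable by construction, so the reduced model reaches
the 90 % validation-accuracy stopping threshold after two epochs; accuracy
1.000 and kappa 1.000 mean every image, including the held-out 64, is
classified correctly. `RNTNetClassifier` follows the scikit-learn estimator
contract (`fit` / `predict` / `predict_proba` / `get_params`), so it
composes with sklearn pipelines, `clone` and model selection.

The calibrated full-size configuration prints its complexity budget:

```bash
$ rntnet complexity
parameters: 20.82 M
forward FLOPs (300x300x3): 5.11 G (2/MAC) | 2.54 G (1/MAC)
```

A command-line interface covers the whole pipeline on image folders
(one sub-directory per class):

```bash
rntnet synth --classes 8 --per-class 40 --seed 7 --out data/
rntnet train data/ --preset reduced --epochs 30 --lr 1e-3 --out runs/demo
rntnet cv data/ --k 5
rntnet sweep data/ --sizes 4,8,16,64,128
rntnet gradcam runs/demo/checkpoint.npz data/class_00/class_00_0000.png class_00
```

Each training run leaves a directory with a YAML config snapshot, per-epoch
CSV log, metrics JSON and an `.npz` checkpoint (weights + resolved config +
class order).

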