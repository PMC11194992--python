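# wolfscan

A toolkit for grey-wolf-optimized deep-learning classification of
Parkinson's disease (PD) versus healthy-control (HC) brain images.  It
provides the building blocks of that workflow as independently testable
components: a from-scratch grey wolf optimization (GWO) engine, a
hyperparameter-search layer that drives any training callback, a
framework-independent builder for five CNN architectures (centered on a
hybrid VGG16 + inception-reduction design with exact feature-map
contracts), a DICOM preprocessing and splitting pipeline, binary-classifier
evaluation metrics, and a deterministic brain-phantom generator so
everything runs end-to-end without access-restricted clinical data.

Intended users: researchers reproducing or extending metaheuristic
hyperparameter tuning for medical-image classifiers, and anyone who needs
a transparent, desk-scale reference for the individual pieces.

## The methods in brief

**Grey wolf optimization.** A population of candidate solutions ("wolves")
minimizes an objective over a box.  The three best solutions — alpha, beta,
delta — steer the rest: for each leader a wolf computes an encirclement

    V = |S · T_leader − T|,    candidate = T_leader − U · V

with stochastic coefficients `U = 2p·q₁ − p`, `S = 2·q₂`, `q₁, q₂ ~ U[0,1]`,
and moves to the mean of its three candidates, clamped to the box.  The
decay `p` falls linearly from 2 to 0 across iterations, shifting the pack
from exploration (`|U| > 1`) to exploitation (`|U| < 1`).

**Hyperparameter search.** GWO moves in a continuous box over learning
rate [0.001, 0.01], batch size [32, 128], momentum [0.9, 0.99], dense
units [128, 512] and epochs [10, 50]; integer dimensions are rounded only
at decode time.  Fitness is `1 − validation accuracy`, memoized per decoded
assignment.

**Hybrid architecture.** A VGG16 backbone (13 convolutions, five 2×2
pools: 224×224×3 → 7×7×512) feeds two inception-reduction blocks
(7×7×640, then 3×3×832 via stride-2 valid reduction, with 7×7 kernels
factorized into 7×1 and 1×7 pairs), a 1×1 projection to 1024 channels,
global average pooling, and a dense head ending in one sigmoid unit.
Shape inference over the layer graph makes these contracts testable
without any deep-learning framework; a NumPy forward-pass adapter
cross-checks every inferred shape against real arrays.

**Preprocessing.** DICOM slices are windowed to 8 bits, near-blank slices
(mean intensity < 30) are removed, the head is masked (Otsu threshold +
largest component + closing), images are cropped, resized to 224×224×3,
and split 80:20 train/test then 80:20 train/validation with
`test = floor(0.2·n)` at each level.

**Evaluation.** Accuracy, sensitivity, specificity, precision, F1 from the
confusion matrix, and AUC by trapezoidal integration of the ROC curve
(equal to pair-counting with ties at half).

## Worked example

```sh
$ python examples/gwo_benchmark.py
iteration   0: best fitness 4.089e+00
iteration  10: best fitness 4.404e-07
iteration  50: best fitness 4.805e-31

best position [0.0, 0.0]
best fitness  4.805e-31
```

Twenty wolves on the 2-D sphere collapse from a random start (fitness ≈ 4)
to numerically zero — the optimizer finds the true optimum at the origin.

```sh
$ python examples/preprocess_phantoms.py
retained 90 images, filtered 10 blanks
label       HC  PD
split
test         9   9
train       30  28
validation   7   7
```

Of 100 generated phantoms, exactly the 10 deliberately blank slices are
removed by the empty-image filter, and the floor-convention split gives
18/14/58 test/validation/train.  The other examples cover architecture
building (`build_architectures.py`), hyperparameter tuning
(`tune_hyperparameters.py`) and classifier evaluation
(`evaluate_classifier.py`).

A thin CLI wraps the same functions: `wolfscan simulate`, `preprocess`,
`split`, `optimize`, `train`, `evaluate`, `gwo-bench`, `model-spec`.

## Layout

- `src/wolfscan/gwo.py` — GWO engine (search space, pack, coefficient
  draws, encircle/hunt updates, optimize loop)
- `src/wolfscan/hpsearch.py` — hyperparameter space, decoding, fitness
  cache, GWO-driven and random-baseline search
- `src/wolfscan/models.py` — layer-graph specs, shape inference, the five
  architecture builders
- `src/wolfscan/adapters.py` — NumPy forward-pass adapter (independent
  shape oracle), optional Keras build hook
- `src/wolfscan/preprocess.py` — DICOM conversion, empty filter, skull
  strip, crop/resize, floor-convention splitter, pipeline driver
- `src/wolfscan/metrics.py` — confusion matrix, score metrics, ROC/AUC
- `src/wolfscan/synthetic.py` — deterministic phantom generator with truth
  manifests
- `src/wolfscan/trainers.py` — desk-scale trainers for the search contract
- `src/wolfscan/cli.py`, `src/wolfscan/config.py` — CLI and YAML config

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
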