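# Methods

This note records the models and procedures wolfscan implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about real data.

## Grey wolf optimization

The engine minimizes a scalar objective over an axis-aligned box.  Each
iteration: the decay coefficient `p = 2(1 − t/t_max)` is computed once and
shared by the whole pack; the pack is ranked (alpha/beta/delta = three
lowest fitnesses, ties broken by wolf index for reproducibility); every
wolf computes one candidate per leader via `V = |S·T_leader − T|`,
`candidate = T_leader − U·V`, and moves to the mean of the three
candidates, projected back onto the box.

Choices where the formulation leaves room:

- **Per-dimension, per-leader coefficient draws.** `q₁`, `q₂` (hence `U`,
  `S`) are drawn independently for every wolf, leader and coordinate.
  This is the common reading of the vector notation and maximizes
  exploration; a scalar-per-wolf variant would couple coordinates.
- **Minimization convention.** Fitness is minimized; callers maximize by
  negation (the hyperparameter layer does exactly this with
  `1 − accuracy`).
- **Boundary handling** is hard projection (clamp), not reflection.
- **Leader snapshot.** Within an iteration all wolves move against the
  same alpha/beta/delta positions (snapshotted before the sweep), so the
  update order of wolves cannot change the result.
- **Global best** is tracked across every evaluation, separately from the
  current alpha, so the returned optimum never regresses even when the
  pack wanders.
- **Randomness** comes from one `numpy` Generator seeded in the config; no
  global state, so identical configs give bit-identical histories.
- An optional absolute fitness `tolerance` enables early stop; the default
  termination is the iteration count alone.

One documented ambiguity: a variant description of the attacking phase
bounds the coefficient by symbols (`r`, `r₂`) that conflict with the
definition `U ∈ [−p, p]`; the engine follows the defining equation.

## Hyperparameter search

The search space is mixed integer/continuous.  GWO itself moves in the
continuous box; decoding rounds integer dimensions half-up and clamps, so
the optimizer's dynamics are untouched by discretization.  Pinned
dimensions (lower == upper) are supported; every position then decodes to
the same assignment and the cache reduces the run to one trainer call.

- **Fitness** is `1 − validation accuracy`; among equal-accuracy
  assignments the lower validation loss wins when the best is selected.
  Accuracy drives selection because that is how the tuned models were
  compared; loss is the natural tie-breaker.
- **Cache.** Assignments are memoized by their decoded values, so the
  trainer-call budget is at most `n_wolves × (n_iterations + 1)` and
  strictly less whenever positions collide after rounding.
- **dense_units** is a single searched integer controlling the first head
  layer; the second is fixed at half of it (matching the 256 → 128 head).
- **momentum under Adam.** Classical momentum is not an Adam parameter;
  the value maps to Adam's first-moment decay (beta₁) when ≥ 0.9 and is
  ignored otherwise.  The mapping is recorded per evaluation in the log.

The bundled `TinyImageTrainer` (scikit-learn MLP on 8×8 mean-pooled,
train-standardized pixel features) exists so the search loop runs in
seconds; it is a desk-scale stand-in for full CNN training, not a claim
about CNN behaviour.  The `make_toy_trainer` response surface
(`accuracy = 1 − ((log₁₀ lr − log₁₀ lr*) / 0.35)²`, clipped at 0) gives a
closed-form optimum for recovery tests.

## Architectures and shape inference

A `ModelSpec` is an acyclic named graph of layers; shapes are inferred
with the standard arithmetic (`same` padding: `ceil(in/stride)`; `valid`:
`floor((in − k)/stride) + 1`; concatenation sums channels and requires
equal spatial dims; global average pooling yields `(1, 1, C)`).

The hybrid model's block contract is 7×7×512 → 7×7×640 → 3×3×832 →
pooled 1024 → one sigmoid unit.  Open points and how they are resolved:

- **Per-branch channel widths** inside the inception-reduction blocks are
  not part of the contract; only the concatenated totals are.  The
  allocations live in one constants table (`_B2_*`, `_B3_*` in
  `models.py`): Block-2 inception branches 64+128+96+64 → 352, reduction
  160+128+352 → 640; Block-3 inception 128+128+128+128 → 512, reduction
  160+160+512 → 832.
- **Projection to 1024.** The pooled vector is specified as length 1024
  although Block-3 emits 832 channels; a 1×1 convolution (832 → 1024)
  before global average pooling is the minimal insertion reconciling the
  two numbers.
- **Reduction strides.** Block-2's reduction runs stride 1 / same (its
  output stays 7×7); Block-3's closes with stride-2 valid stages (7 → 3).
- **Head.** dense(256)+BN+dropout(0.2) → dense(128)+BN+dropout(0.2) →
  dense(1, sigmoid).  A binary task trained with binary cross-entropy
  needs the single sigmoid unit; batch normalization follows each hidden
  dense layer.
- **DenseNet-121 and the InceptionV3 stem** are treated as standard,
  configurable backbones: DenseNet is built with the usual 6/12/24/16
  blocks (growth 32, half-channel transitions, 7×7×1024 out); the
  InceptionV3-style network uses the 32/32/64-filter stem followed by
  representative inception modules.  Their internals are not a
  contribution here and only the stated facts (stem filters, head) are
  contract-tested.
- **DenseNet+LSTM sequencing.** The final 7×7×1024 feature map's rows
  become 7 timesteps of 7·1024 features feeding one LSTM layer of width
  128 — the simplest spatial-to-sequence mapping.
- The VGG16 description elsewhere mentions 6×6 filters after pooling;
  this contradicts the 3×3 statement and standard VGG16, so 3×3 is used.

The NumPy adapter (`adapters.NumpyModel`) executes a spec with
random-initialized weights (im2col convolutions, window pooling, a
standard LSTM recurrence).  Because it derives shapes from concrete
arrays, it is an independent oracle for the symbolic inference; the two
are compared layer-by-layer in tests and in the acceptance script.  A
Keras build hook exists for users with tensorflow installed.

## Preprocessing

- **Empty-slice rule.** "Empty" is operationalized as mean 8-bit
  intensity below the threshold (default 30).  This reads the intensity
  threshold as a slice-level criterion on near-blank arrays, and is
  logged per file so the rule is auditable.
- **Windowing.** Stored DICOM values are mapped linearly through the
  file's window (center/width, after rescale slope/intercept) to [0, 255];
  without window tags the min-max range is used.
- **Skull stripping** is Otsu threshold → largest connected component →
  morphological closing (padded so the border cannot erode) → hole fill.
  It is a transparent, testable procedure, not a clinical-grade tool.
- **Crop/resize**: bounding box of the head mask, square-padded, bilinear
  resample to 224×224, grey replicated to 3 channels.
- **Split convention**: `test = floor(0.2·n)`, then
  `validation = floor(0.2·(n − test))`.  This reproduces the published
  totals at every level (9070 → 7256/1814; 7256 → 5805/1451;
  20096 → 16077/4019; 16077 → 3215).  Stratification by class is
  best-effort (largest remainder) because the totals, not per-class
  counts, are the fixed quantity; the published per-class counts are
  internally inconsistent with their own totals, so totals govern.
  Slice-level splitting is the default (it reproduces those totals); a
  subject-level mode keeps all slices of a subject together for
  leakage-safe evaluation.
- PNG output is the default (lossless); JPEG quality 95 is available.

## Evaluation

The five scores follow the confusion-matrix definitions; zero-denominator
cells return 0 with a warning flag so batch evaluation never raises.  AUC
is the trapezoid over the threshold-swept ROC, which equals
Mann–Whitney pair counting with ties at half; the default decision
threshold on sigmoid scores is 0.5.

## Synthetic phantoms

Each phantom is a 256×256, 12-bit image: an elliptical skull ring
(intensity 3000), textured interior tissue (1200 ± smoothed noise), and
two striatal foci whose mean amplitude is 1600 for HC and
1600 − separation (default 600) for PD, with per-image jitter (s.d. 80).
HC foci are elongated ("comma"), PD foci round ("dot").  A configurable
fraction of slices (default 10%) is written blank to exercise the empty
filter.  DICOMs are 16-bit monochrome with a linear window so the
conversion path is exercised; UIDs and dates are deterministic functions
of the seed so fixed seeds give byte-identical files.

The defaults were chosen so that (a) a scalar threshold on focus
amplitude separates the classes with ≥ 0.9 accuracy (the closed-form
midpoint between two Gaussians 600 apart with s.d. 80 is essentially
error-free, and the pooled-pixel trainer sees a correspondingly strong
signal), and (b) the head mask is trivially recoverable by thresholding,
so skull-strip failures indicate bugs rather than hard images.

What passing tests show: the pipeline's mechanics (filtering, masking,
geometry, splits, determinism) and the optimizer's behaviour on a real
learnable signal.  What they do not show: performance on clinical MRI or
SPECT data — phantoms have no anatomy, no scanner artifacts, no 3-D
structure, and a far cleaner class signal than real DaTscan uptake.

## Problem sizes

Tests and the acceptance script run at desk scale by design: phantom sets
of 100 images, search budgets of 5 wolves × 5 iterations (30
evaluations), GWO convergence checks with 20 wolves × 50 iterations over
20 seeds, and the GWO-versus-random comparison over 10 seeds with an
equal 30-evaluation budget per method.  These sizes are the package's own
reference conditions; the components scale to larger inputs unchanged.

## Known limitations

- The NumPy adapter is inference-only; training at scale requires the
  optional Keras path and a GPU.
- The skull stripper assumes a single bright head on a dark background.
- AUC on hard labels (rather than scores) degenerates to one ROC vertex.
- The subject-level split mode fills test, then validation, then train by
  whole subjects, so its sizes only approximate the floor rule.
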