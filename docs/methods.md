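# Methods

This note documents the models, parameter choices, and numerical decisions
behind `retinopatch`, and what the synthetic-data experiments do and do not
demonstrate.

## Patch geometry

The canvas is fixed at 256 × 256 (resized anisotropically; no letterboxing,
no retina-specific preprocessing such as border cropping or illumination
correction). Quadrants are cut at row/column 128; the cut direction per
quadrant is fixed — horizontal (wide 64 × 128 strips) in the upper-left and
lower-right quadrants, vertical (tall 128 × 64 strips) in the upper-right
and lower-left. Patch order is P1,P2 = UL top/bottom, P3,P4 = UR left/right,
P5,P6 = LL left/right, P7,P8 = LR top/bottom, with 0-based half-open
coordinate ranges. The order and the within-quadrant convention
(top-before-bottom, left-before-right) are fixed so that feature-column
provenance is stable across runs and implementations. The eight patches
partition the canvas exactly; this is asserted property-style on random
images.

## Embedding backends

A backend maps one 3-channel image to a pair of vectors: the activations of
a 1000-way classification layer ("fc", read before the softmax) and of a
global-average-pool layer ("pool", 1920-d for DenseNet201). Non-square
patches are resized (bilinear) to the backend's square input side — 224 for
DenseNet201 — matching standard transfer-learning practice; inputs are
scaled to [0, 1] and standardized with the ImageNet channel statistics the
pretrained weights assume. The DenseNet201 backend is optional (torch /
torchvision extra) and is never needed by the test suite.

The stub backend used throughout testing converts the image to grayscale
(channel mean), downsamples to 32 × 32, and applies two frozen random
Gaussian projection matrices (no bias) drawn once from its seed. It is
exactly linear in the downsampled intensities, deterministic, and — being a
random projection — approximately preserves the geometry of the image
distribution, so class structure that is decodable from 32 × 32 grayscale
survives into the 26,280-feature space.

## Regularized NCA for feature selection

Per-feature weights w ≥ 0 are fitted to maximize expected leave-one-out
accuracy of a softmax-over-distances neighbor model with the weighted L1
distance d_w(xᵢ,xⱼ) = Σ_l w_l²|x_il − x_jl|, minus an L2 penalty λ‖w‖².
Defaults: λ = 1/n, σ = 1, w initialized to all ones, mini-batch gradient
ascent (batch 32, learning rate 0.1 decaying as 1/(1+epoch), at most 100
epochs, early stop when the full-data objective improves by less than
1e−6). The seed is mandatory; fits are bitwise reproducible.

Numerical choices:

- Softmax rows are stabilized by subtracting the row-wise maximum of the
  negated scaled distances; p_ii = 0 by construction.
- Because w ≥ 0, w_l²|a−b| = |w_l²a − w_l²b|, so pairwise distances are
  computed as a cityblock distance on the column-scaled matrix (a single C
  call, no n × n × D temporary). The gradient accumulates |x_il − x_jl|
  over feature chunks of 2,048 columns to bound memory.
- Weights are clipped at 0 after every step, which also makes the top-k
  ordering well-defined; ties are broken by ascending column index.
- Batches containing a single class contribute no gradient and are skipped.
- **Kernel width σ**: with D in the tens of thousands the initial weighted
  L1 distances grow linearly in D, the softmax collapses to a hard nearest
  neighbor, and gradients vanish (the exponent is far from order 1).
  `sigma="auto"` therefore resolves, once per fit at the initial weights,
  to the mean off-diagonal weighted distance, keeping the exponent O(1) at
  any dimensionality. The numeric default stays σ = 1, which is the
  standard choice at moderate D (the planted-matrix experiments, D = 50,
  use it); pipeline runs on the 26,280-column matrix use `auto`.

Correctness is established against two independent oracles: a literal
double-loop enumeration of the objective (agreement to 1e−10 relative) and
central finite differences for the gradient (max relative deviation below
1e−4, observed ~1e−11). On planted matrices (n = 200, D = 50, 10
informative columns shifted by 1.5 SD per class step), the top-10 selection
recovers ≥ 8 planted columns in ≥ 80% of 20 seeds (observed: 20/20).

## Normalization/selection leakage policy

The reference protocol normalizes and runs NCA on the **full dataset**
before any validation split (`paper_faithful` mode); its scores are
optimistic because selection has seen the test rows. `leakage_safe` mode
re-fits min–max and NCA inside every training partition and is the mode to
use for honest generalization estimates. Both are first-class, logged, and
hash-stamped, because the distinction changes results and silently
conflating them is the classic failure mode of selection-then-validate
pipelines.

## Cubic SVM and evaluation

The classifier is sklearn's SVC with the polynomial kernel
K(u,v) = (coef0 + u·v/s)³, coef0 = 1, box constraint C = 1, one-vs-one
multiclass, inputs standardized inside the model. `kernel_scale="auto"`
resolves to the feature count (the `gamma='scale'` convention for
standardized inputs), so the scaled inner product has unit order of
magnitude. Degree 3 is the published configuration; other degrees are
accepted but flagged as departures.

Hold-out uses a single stratified 80:20 split. 10-fold CV is stratified
with shuffling; out-of-fold predictions are **pooled into one confusion
matrix** (per-fold matrices are retained) — a pooled matrix is what a
single reported confusion figure implies, and pooled metrics are exact
functions of it. Classes with fewer than 2 (hold-out) or 10 (CV) samples
raise contract errors rather than degenerate splits.

Metric panel from a C × C confusion matrix (rows = truth): accuracy;
unweighted average recall and precision (empty row/column → 0); macro F1
(0 where P + R = 0); Cohen's kappa with p_e from row/column marginals
(κ = 1 for a perfect single-cell matrix); geometric mean of class-wise
recalls with no epsilon smoothing — one fully missed class sends gmean to
0 by design, which is exactly the imbalance sensitivity the metric is for.
All metrics are computed on proportions and also reported ×100 at 2
decimals. The hand-rolled panel is cross-checked in the tests against
sklearn's metric functions computed from raw predictions.

## Synthetic fundus generator

The generator exists so that every stage — and the pipeline end to end —
is testable offline with a known ground truth. It emulates the *decision
structure* of DR grading, not its photographic appearance:

- **Standardized acquisition.** Protocol fundus photography frames the
  retina reproducibly, so the disc geometry is held nearly fixed and only
  a mild global illumination shift (which also affects the background, and
  can therefore be referenced away) varies between shots.
- **Stereotyped vasculature.** Retinal arcades are anatomically similar
  across eyes: the vessel tree is a per-dataset template (a fan of
  curvilinear walks leaving the optic disc, steered inside the retina and
  around the avascular macular zone) with only small per-image jitter.
  Inter-image vascular variation is nuisance, not signal, and is kept
  deliberately small.
- **Grade signs.** Class g draws Poisson(6g) hemorrhage-like dark blots
  (peripheral annulus) and Poisson(3g) hard-exudate-like bright dots
  (macular zone, as in clinically significant macular edema); venous
  caliber increases with grade (dilation/beading is a cardinal
  non-proliferative sign); and the top grade adds neovascular tufts at the
  optic disc — the defining finding of proliferative disease. Grade 0 has
  no lesions. Pixel noise is Gaussian (SD 2).

Because lesion counts are Poisson, count information alone caps 3-class
accuracy near 0.87 (adjacent grades overlap by ~2 SD); the structural
signs (caliber, tufts) are what make near-perfect grading possible, just
as real clinical grading rests on structural findings and not only lesion
counting. Passing the end-to-end test therefore shows that the pipeline
recovers linearly-decodable and structural class signal through
patchification, random-projection embedding, NCA selection, and the cubic
SVM — it does **not** show that the pipeline grades real photographs at
any particular accuracy, and the generator makes no photorealism claim
(no texture, no camera vignetting, no inter-subject anatomy variation).

The planted-matrix generator (Gaussian noise, a known informative column
subset shifted by `effect_size` per class step, balanced labels) is the
ground-truth harness for the selection stage alone.

## Problem sizes

End-to-end experiments use 150 images (3 × 50, generator seed 42 in the
test suite), the full 26,280-column matrix, k = 500, and 10 NCA epochs
with `sigma="auto"` — at this width the objective plateaus within a few
epochs and 10 keeps the full run under a minute. The planted-recovery
study uses 20 seeds at n = 200, D = 50 with the 100-epoch default.

## Known limitations

- The DenseNet201 path is implemented but exercised only by its contract
  (dimensions, normalization, error behavior); no pretrained-weight
  regression test exists because weights are an optional download.
- NCA uses mini-batch ascent with a decaying step; the trace is
  non-decreasing in practice but no line search guarantees monotonicity.
- `paper_faithful` scores on small datasets can be strongly optimistic;
  use `leakage_safe` for generalization claims.
- The synthetic generator's nuisance model is deliberately mild; real
  fundus datasets (camera variation, field of view, ungradable images)
  are far harder, and stub-backend results do not transfer to them.
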