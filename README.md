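# retinopatch

Patch-division deep-feature engineering for grading diabetic retinopathy
(DR) from fundus photographs.

Diabetic retinopathy is graded on color photographs of the retina by the
lesions it produces: microaneurysms and hemorrhages (dark), hard exudates
(bright), venous changes, and — in the proliferative stage — new abnormal
vessels. `retinopatch` implements a classical feature-engineering pipeline
for this problem: instead of training a CNN end to end, it reads a frozen
pretrained network as a feature generator over a fixed set of image regions
and lets a shallow classifier do the rest. The package is aimed at
researchers who want a reproducible, fully inspectable baseline of this
family — every stage is a plain function with a documented contract, and a
synthetic data generator makes the whole pipeline testable offline.

## Pipeline

For each image:

1. **Resize** to a 256 × 256 canvas.
2. **Patchify**: split into four 128 × 128 quadrants; cut the upper-left and
   lower-right quadrants horizontally (two 64 × 128 strips each) and the
   upper-right and lower-left quadrants vertically (two 128 × 64 strips
   each) — eight oriented patches P1..P8 that tile the canvas exactly.
3. **Embed** the main image and every patch with a frozen backend. With
   DenseNet201 the `fc1000` (pre-softmax logits, 1000-d) and `avg_pool`
   (1920-d) layers give 2,920 features per input, hence a concatenated
   vector of **D = 9 × 2,920 = 26,280** features per image.
4. **Normalize** each feature to [0, 1] (min–max).
5. **Select** the top *k* = 500 features by regularized neighborhood
   component analysis (NCA): per-feature weights w ≥ 0 maximize

   F(w) = (1/n) Σᵢ pᵢ − λ ‖w‖²,  with
   d_w(xᵢ, xⱼ) = Σ_l w_l² |x_il − x_jl|,
   p_ij = exp(−d_w(xᵢ,xⱼ)/σ) / Σ_{k≠i} exp(−d_w(xᵢ,x_k)/σ),
   pᵢ = Σ_{j : y_j = y_i} p_ij,

   the expected leave-one-out accuracy of a stochastic nearest-neighbor
   rule, fitted by seeded mini-batch gradient ascent.
6. **Classify** with a cubic SVM — one-vs-one, kernel
   K(u, v) = (1 + u·v/s)³ — and evaluate with stratified 80:20 hold-out and
   stratified 10-fold cross-validation, reporting accuracy, unweighted
   average recall/precision, macro F1, Cohen's kappa, and the geometric
   mean of class-wise recalls from the (pooled) confusion matrix.

The embedding backend is pluggable: `densenet201` (needs the optional
`torch`/`torchvision` extra) for real photographs, and a deterministic
`stub` (seeded random linear projection of the 32 × 32 grayscale image)
that keeps the whole pipeline fast and exactly reproducible for testing.

## Worked example

No data is required — the synthetic generator emulates graded fundus
images (normal / non-proliferative / proliferative):

```bash
cat > run.yaml <<'YAML'
workdir: runs/demo
backend: stub
k: 500
mode: paper_faithful
protocols: [holdout8020, cv10]
synth: {n_per_class: 50, n_classes: 3, seed: 42}
nca: {seed: 0, max_epochs: 10, sigma: auto}
svm: {seed: 0}
split_seed: 0
YAML
retinopatch run --config run.yaml
```

prints

```
holdout8020: {"accuracy": 96.67, "uar": 96.67, "uap": 96.97, "macro_f1": 96.66, "kappa": 95.0, "gmean": 96.55}
cv10: {"accuracy": 98.0, "uar": 98.0, "uap": 98.0, "macro_f1": 97.99, "kappa": 97.0, "gmean": 97.99}
```

i.e. on 150 synthetic images the selected 500-of-26,280 features separate
the three grades almost perfectly under both protocols (chance is 33.3%;
kappa and gmean near 100 mean no class is sacrificed). The run directory
holds `features.npz` (the 150 × 26,280 matrix with column provenance),
`selection.json` (indices, weights, NCA trace), and one report JSON plus a
confusion-matrix CSV per protocol, all stamped with the config hash.
Subcommands `synth`, `extract`, `select`, and `evaluate` expose the stages
individually; `--mode leakage_safe` re-fits normalization and selection
inside every training partition instead of on the full dataset (see
`docs/methods.md` for why both modes exist).

To run on real photographs, point the config at a directory of PNG/JPEG
files with a `labels.csv` (`filename,label` header) and set
`backend: densenet201`.

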