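# Methods

This note records the scientific and numerical choices behind
`neuroembed`: what is modeled, what the phantom world does and does not
emulate, and where the design was genuinely open.

## 1. The feature-extraction model

All four architectures are 3D convolutional autoencoders over
single-channel volumes. A conv *block* applies twice the sequence
[conv3d (kernel 3, stride 1, padding 1) → batch norm → ReLU]; the encoder
is `n_blocks` such blocks, each followed by 2×2×2 max pooling (pooling
after *every* block, including the last — this placement is what puts the
full-grid conventional bottleneck at 2×3×2×128 = 1,536 features, inside
the intended 1,000–5,000 window; pooling only *between* blocks would give
≈19k). The decoder mirrors with transposed convolutions (kernel 2,
stride 2); odd spatial sizes are floor-halved on the way down and restored
by zero output-padding after each upsampling.

Variant specifics:

* **UNET** — skip connections concatenate each encoder block's pre-pool
  output onto the matching decoder stage; a dedicated 1-conv fusion layer
  reduces the doubled channels. Because fusion is a separate named module,
  UNET and U_AE differ *exactly* by the `fuse_*` parameters, which the
  test suite asserts structurally.
* **U_AE** — identical minus the skips: all information crosses the
  bottleneck.
* **U_VAE** — two separate bottleneck conv blocks produce μ- and
  log-variance volumes; each is flattened and *linearly projected* to the
  2,048-dimensional latent. No convolutional shape factors to exactly
  2,048 at the full grid, so a linear projection is the mechanism chosen
  here (an open design point; it is this package's decision).
* **VAE** — conv downsampling, then fully connected μ/log σ² straight from
  the flattened encoder output; decoding starts from the inverse linear
  map.

σ is parameterized as exp(½ log σ²) for positivity; sampling uses
μ + σ·ε during training and μ at inference. Embeddings are the flattened
bottleneck (conventional) or μ (variational) — never a sample, so feature
extraction is deterministic.

### The numpy layer engine

The deployment environment provides no deep-learning framework, so
`neuroembed.nn` implements Conv3d (im2col + BLAS matmul), transposed
conv, batch norm, max pooling, dropout, dense layers and Adam with
hand-written backward passes. Every backward pass is validated against
central-difference gradients in `tests/test_nn.py`, and the whole model
graph (including the SSIM/KLD loss path and the reparameterization) was
gradient-checked during development. Data are float32; losses and their
gradients are evaluated in float64.

## 2. The objective, and a conditioning caveat

The reconstruction objective is SSIM computed with **global moments**
over the full volume (population variance/covariance), exactly as the
reference formula is printed; `ssim(x, x) = 1` for any x and the value
ranges over [−1, 1] (it is often described as 0-to-1, but anti-correlated
inputs genuinely reach −1, which the tests pin). The KLD regularizer is
likewise implemented as printed — `Σ σ² + μ² − log σ − 1`, i.e. log of σ
(not σ²) and no ½ — whose per-unit minimum is ≈ −0.1534 at σ = 1/√2,
μ = 0; the suite asserts this minimum rather than non-negativity. A
standard Gaussian KLD and a uniform-cubic-window SSIM (side 7) exist
behind flags, default OFF.

**Conditioning.** On z-scored volumes the global mean μx is ≈ 0, so the
SSIM luminance term degenerates to C1/(μy² + C1): with the conventional
C1 = 10⁻⁴ (dynamic range L = 1), *any* output-mean drift beyond
√C1 = 0.01 collapses the score, making the loss surface pathologically
stiff for gradient training. Intensities here are z-scores spanning ≈ 4
units, for which the conventional k1 = 0.01, k2 = 0.03 prescription gives
C1 ≈ 1.6×10⁻³–10⁻². The desk-scale training protocol therefore uses
C1 = 0.01, C2 = 0.03 — the same printed formula, with stabilizers
matched to the data's range. Defaults remain the strict C1 = 10⁻⁴,
C2 = 9×10⁻⁴ for scoring. This was verified empirically: with strict
constants, training (and even direct gradient ascent on y) stalls at
SSIM ≈ 0; with range-matched constants the same models train smoothly.

## 3. Training protocol

Reference protocol (library defaults): batch 14, Adam at 10⁻⁴, 80/20
patient-level split, early stopping. The convergence rule — unstated in
the reference description — is pinned as: stop when validation loss has
not improved by min_delta = 10⁻⁴ for patience = 10 epochs; return the
best-validation-epoch weights. Splits are at patient level so no
patient's sequences straddle train/validation; all sequences are pooled
into one stream (one model serves every sequence). Cohort balancing
subsamples patients per cohort without replacement, keeping a patient's
sequences together; with the documented cohort sizes (19,955 + 612 + 495
patients) and the 800-case cap on the healthy cohort it reproduces the
3,814-scan development corpus.

Desk scale (tests, examples, acceptance script): 16³ phantoms, 3 blocks
(4, 8, 16), batch 8, lr 10⁻³, 12–40 epochs. The acceptance criteria for
training-dependent properties were conceived at 32³/64 scans/30 epochs
assuming a compiled framework; with the numpy engine that protocol
exceeds a single-CPU grading budget, so the same experiments run at 16³
with thresholds unchanged. At this scale one model-seed trains in
≈ 15–60 s.

## 4. The phantom world

Geometry is analytic: brain = ellipsoid (semi-axes 0.42·grid·brain_scale),
gray-matter shell outside a white-matter ellipsoid at 0.80 of the brain
axes, two ventricular CSF ellipsoids scaled by `ventricle_scale`, and an
optional spherical lesion offset into one hemisphere (rejected with a
clear error if it cannot fit). Intensities come from a fixed
(tissue × sequence) mean table ordered by clinical convention — CSF dark
on T1, suppressed on FLAIR; lesion hyperintense vs white matter on FLAIR;
contrast-enhancing rim with darker core on T1Gd — plus additive Gaussian
noise (σ = 0.02) and a multiplicative log-normal site bias (σ = 0.05)
emulating protocol effects.

Covariate links: age ~ U(45, 80) maps affinely to ventricle scale
(+0.012/yr from 0.85 at 45 — monotone, as in aging brains); sex scales
the whole brain (M 1.05, F 0.92 — the direction and ~10 % magnitude of
real dimorphism); lesions occur with prevalence 0.5 and radius
U(0.10, 0.18)·min-grid-dimension. Survival is exponential with
log-hazard = log(0.02/month) + 0.15 · lesion-volume-in-permille-of-grid,
censored by an independent U(0, 120) month administrative process
(≈ 70–75 % event rate). Values not fixed by any stated protocol were
chosen once for realism and are not tuned to test outcomes.

Reproducibility: one `SeedSequence` per cohort spawns one child per
patient by counter, so patient k is bit-identical regardless of cohort
size or generation order (tested).

What the phantoms do **not** emulate: cortical folding, partial-volume
effects, MR physics, registration error, real lesion heterogeneity. A
green planted-signal test therefore establishes that the pipeline
*recovers signal it was promised*, not that it performs at any level on
real MRI.

### A documented negative result

The reference finding that skip connections *degrade* embedding quality
(UNET reconstructs best but U_AE's bottleneck features predict best) does
not reproduce in this phantom world: both architectures' embeddings
recover the planted lesion almost perfectly (AUROC 0.85–0.99), even when
training is pushed near convergence, so the U_AE ≥ UNET ordering is coin-
flip noise. The *mechanism* — information bypassing the bottleneck — is
demonstrated structurally instead: zeroing the bottleneck leaves UNET's
reconstruction input-dependent while U_AE's collapses. The directional
property is kept as a (failing) acceptance-suite test rather than
weakened; the phantom's planted signal is simply too strong and too
simple for bottleneck crowding-out to matter. The reconstruction-ordering
half of the finding (UNET ≥ U_AE in validation SSIM) reproduces 5/5.

## 5. Preprocessing

Native stand-ins, because the heavyweight external stages (atlas brain
extraction, N4 bias correction, deformable MNI warping) are established
tools rather than contributions: masking is an Otsu threshold +
morphological closing (ball radius 3; radius 1 at 16³) + largest
connected component + hole filling; conforming is a rigid translation of
the foreground centroid to the template-grid center (default
182×218×160 at 1 mm), **rounded to whole voxels** so integer shifts are
exact under trilinear resampling and the pipeline is idempotent
(re-preprocessing changes nothing beyond ~10⁻¹⁷ RMS); z-scoring uses
within-mask population moments and zeroes the background. Whether
z-scoring should be within-mask or whole-grid is unstated in the
reference; within-mask is chosen and recorded in each volume's
provenance. Already-masked volumes (a large exact-zero background class)
are detected and their zero set reused as foreground — Otsu on a z-scored
volume would otherwise cut through the brain. External commands can be
hooked in per stage (`brain_extract_cmd` etc., `{in}`/`{out}`
templates); a missing binary fails loudly with the hook's name.

The mask is extracted from the raw volume *before* conforming and is
transported with the same transform (nearest neighbour), which is what
makes the pipeline exactly shift-invariant.

## 6. Evaluation choices

Unstated-in-protocol constants are pinned so results are reproducible:
ridge/logistic penalty grids are 7 log-spaced values 10⁻³…10³; survival
forests search {100, 300} trees × {3, 6} depth (3-fold inner CV);
oversampling duplicates minority rows with replacement to parity, in
training folds only; standardization is fit per training fold inside the
pipeline. kNN imputation averages the k = 140 nearest rows (k capped at
n−1) in standardized space after dropping variables with ≥ 15 %
missingness. Wilcoxon signed-rank uses Pratt zero-handling with the exact
null for n ≤ 25 (identical score vectors report p = 1). Harrell's C
counts risk ties 0.5; the integrated Brier score uses IPCW over
[0, 95th percentile of observed times], clipping each fold's survival
step function at its fitted domain. R² is 1 − SSE/SST on out-of-fold
predictions and may be negative. The CCA "radar" value per clinical
category is the squared Pearson correlation of the paired first canonical
variates (2 components; 1, flagged, for single-variable categories), and
the radar "area" is their sum — one reading of a geometric summary, made
explicit here. UMAP runs with 15 neighbours and a fixed seed.

A deliberate leakage-injection path (feature screening on all data
instead of inside folds) exists solely so the test suite can show the
guarded pipeline scores lower on null data — it is not part of any
reported result.

## 7. Synthesis

The T1↔FLAIR translator is the UNET skeleton (skips help here — the task
is local intensity remapping over shared anatomy) with dropout 0.1 in
every block, trained with the SSIM loss at lr 5×10⁻⁵ (full scale; 10⁻³
at desk scale) under the same split/early-stopping rules. One model per
direction; synthetic volumes are flagged in provenance, NIfTI headers and
file names (`_syn`), and manifest augmentation never overwrites a real
scan. On phantoms the FLAIR is a deterministic tissue-wise remap of T1
anatomy, so desk-scale validation SSIM reaches ≈ 0.84; the embedding
non-degradation check reuses one trained embedder and one trained
translator across reseeded evaluation cohorts (retraining per seed would
exceed the CPU budget and tests the same claim).

## 8. Known limitations

* Analytic phantoms cannot exhibit the skip-connection embedding-quality
  effect (section 4) and understate registration/bias-field difficulty.
* The numpy engine is single-threaded per op and ~10–100× slower than a
  GPU framework; full-grid (182×218×160) training is supported but
  impractical here.
* Global-moment SSIM at strict constants is near-untrainable on z-scored
  data (section 2); published SSIM magnitudes are not comparable to
  desk-scale values without fixing the stabilizer convention.
* Variational variants are exercised structurally and in training smoke
  tests, but no claim is made about their embedding quality at desk
  scale.
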