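# neuroembed

Unsupervised, general-purpose embeddings of multi-sequence 3D brain MRI,
built and exercised end to end on a synthetic brain-phantom cohort.

## The problem

Brain MRI volumes are enormous (the standard 1-mm template grid is
182 x 218 x 160 ≈ 6.3 million voxels per sequence) and clinical protocols
are multi-sequence (T1, T1Gd, FLAIR). Training a separate deep model per
clinical question is data-hungry and generalizes poorly. An alternative is
a single unsupervised *feature extractor*: an autoencoder trained only to
reconstruct scans, whose bottleneck activations become a compact per-patient
**embedding** that ordinary models (ridge/logistic regression, random
survival forests) can consume for any downstream question.

`neuroembed` implements that workflow for people who want to study it
mechanistically: the four candidate 3D autoencoder architectures, the exact
reconstruction objective, the preprocessing standardization, patient-level
embedding construction, cross-modality (T1↔FLAIR) synthesis to restore
missing sequences, and a task-typed evaluation harness — plus a seeded
phantom generator that plants known morphological and clinical signal so
every claim is testable on a desk.

## The model

Four architectures share one convolutional skeleton — n encoder blocks
(each block: twice [3D conv k3 s1 p1 → batch norm → ReLU]) with 2×2×2 max
pooling, a bottleneck, and a mirrored transposed-convolution decoder, with
channels expanding (4, 8, 16, 32, 64, 128):

| variant | bottleneck | skips | embedding |
|---|---|---|---|
| `UNET`  | conv block | yes | flattened bottleneck (1,536 at full grid) |
| `U_AE`  | conv block | no  | flattened bottleneck (1,536 at full grid) |
| `U_VAE` | 2 conv blocks → μ, log σ → linear | no | μ (2,048) |
| `VAE`   | fully connected μ, log σ | no | μ (2,048) |

Training minimizes a structural-similarity loss, with a Kullback–Leibler
regularizer for the variational variants:

```
SSIM(x,y)  = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))
SSIM_loss  = (1/n) Σᵢ (1 − SSIM(xᵢ, yᵢ))
KLD_loss   = Σᵢ σᵢ² + μᵢ² − log(σᵢ) − 1
L          = SSIM_loss + β · KLD_loss ,   β = 10⁻⁴
```

SSIM uses global moments over the whole volume (a windowed variant exists
behind a flag), and the KLD term is implemented exactly as written — note
the log of σ and the missing ½, which make its per-unit minimum ≈ −0.153
rather than 0. Because there is no deep-learning framework in the target
environment, the 3D layers, backprop and Adam are implemented in numpy
(`neuroembed.nn`) and verified against numerical gradients.

A patient's embedding is the concatenation of per-sequence feature vectors
in canonical (T1, T1Gd, FLAIR) order. The evaluation harness predicts each
typed clinical variable out of fold (5-fold CV, per-fold grid search,
minority oversampling in training folds only) and scores weighted F1/AUROC,
R², or Harrell's C-index + integrated Brier score; methods are compared by
exact Wilcoxon signed-rank tests with Bonferroni correction, and embeddings
are summarized by per-category CCA "radar" areas and 2-D UMAP projections.

## A worked example

```bash
python examples/04_embeddings.py
```

trains a tiny skip-free autoencoder (16³ phantoms, 3 blocks) on 32 phantom
patients, embeds a fresh 80-patient cohort, and prints:

```
embedding matrix: 80 patients x 256 features (128 per sequence)
out-of-fold lesion AUROC: 1.000 (1.0 = the embedding separates lesioned brains perfectly)
```

The AUROC is computed on concatenated out-of-fold predictions, so it
measures whether the *unsupervised* embedding carries the planted lesion
signal — the core claim of the workflow, reproduced at desk scale. The
other examples (`examples/01...07`) each demonstrate one capability:
phantom generation, preprocessing, training dynamics, synthesis,
the evaluation harness, and the config-driven end-to-end pipeline.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch: it simulates a seeded
phantom cohort, preprocesses it, trains the default tiny skip-free
autoencoder, extracts patient embeddings, evaluates every typed clinical
variable, prints the metrics table, and writes the results JSON to `--out`.

## Layout

```
src/neuroembed/
  phantoms.py        seeded multi-sequence phantom cohorts + covariate links
  io_preprocess.py   NIfTI I/O, masking, conforming, z-scoring, hook points
  nn.py              numpy 3D conv layer engine (manual backprop, Adam)
  models.py          UNET / U_AE / U_VAE / VAE + embedding_dim arithmetic
  losses.py          SSIM / KLD / combined objectives with gradients
  training.py        balancing, patient-level splits, training loop
  embeddings.py      per-sequence extraction, canonical concatenation
  synthesis.py       T1↔FLAIR U-Net translator + manifest augmentation
  evaluation.py      typed CV prediction, survival, comparisons, CCA, UMAP
  workflow.py        strict config, staged pipeline, provenance records
```
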