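"""Train a tiny skip-free autoencoder (U_AE) on phantom scans and watch
the SSIM reconstruction loss fall.

Desk-scale settings: 16**3 grids, 3 blocks with channels (4, 8, 16),
Adam at 1e-3 with SSIM stabilizers suited to z-scored intensities.
The full-scale protocol (batch 14, lr 1e-4, 6 blocks to 128 channels,
grid 182x218x160) is the library default but needs hours of CPU.
"""

import numpy as np

from neuroembed.losses import LossConfig, SSIMParams
from neuroembed.models import AutoencoderConfig, build_model, embedding_dim
from neuroembed.phantoms import CovariateModel, generate_preprocessed_cohort
from neuroembed.training import TrainConfig, train_autoencoder

arrays, cohort = generate_preprocessed_cohort(
    32, CovariateModel(), sequences=("T1",), seed=11, grid_shape=(16, 16, 16))
data = arrays["T1"]

config = AutoencoderConfig("U_AE", input_shape=(16, 16, 16), n_blocks=3,
                           channel_schedule=(4, 8, 16))
print(f"U_AE embedding dimension: {embedding_dim(config)} "
      "(bottleneck 2x2x2 x 16 channels)")

# patient-level 80/20 split (here arrays are one scan per patient, in
# patient order, so positional slicing matches the manifest split)
manifest = cohort.manifest[cohort.manifest.sequence == "T1"].reset_index(drop=True)
n_train = int(round(0.8 * len(manifest)))
model = build_model(config, seed=0)
model, history = train_autoencoder(
    model, manifest[:n_train], manifest[n_train:],
    TrainConfig(batch_size=8, learning_rate=1e-3, max_epochs=15, patience=15),
    LossConfig(ssim_params=SSIMParams(C1=0.01, C2=0.03)),
    train_data=data[:n_train], val_data=data[n_train:])

print("\nepoch  train_ssim_loss  val_ssim_loss")
for _, row in history.iloc[::3].iterrows():
    print(f"{int(row.epoch):5d}  {row.train_ssim_loss:15.3f}  "
          f"{row.val_ssim_loss:13.3f}")
best = history.attrs["best_epoch"]
print(f"\nbest epoch {best}: validation SSIM = "
      f"{1 - history['val_ssim_loss'].iloc[best]:.3f} "
      "(1.0 would be a perfect reconstruction)")
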