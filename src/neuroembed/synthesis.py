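"""Cross-modality MRI synthesis (T1 <-> FLAIR).

A standard 3D U-Net WITH skip connections — here reconstruction
fidelity is the goal, so skips help rather than hurt — mapping one
preprocessed sequence to another.  Blocks are the shared conv-block
design plus dropout (rate 0.1, training only); training minimizes the
SSIM loss between synthesized and real target volumes with Adam at
5e-5 and the same patient-level 80/20 split and early stopping as
autoencoder training.  One model per direction: the two directions are
independent checkpoints rather than a shared conditioned network.

Synthetic outputs are always flagged (``synthetic=true`` in provenance
and the NIfTI description field; file suffix ``_syn``) and never
overwrite real scans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses as L
from .io_preprocess import Volume, read_volume, write_volume
from .models import Autoencoder, AutoencoderConfig
from .training import TrainConfig, split_scans, train_autoencoder

DIRECTIONS = ("T1_to_FLAIR", "FLAIR_to_T1")


@dataclass(frozen=True)
class SynthesisConfig:
    direction: str = "T1_to_FLAIR"
    input_shape: tuple = (182, 218, 160)
    n_blocks: int = 6
    channel_schedule: tuple = (4, 8, 16, 32, 64, 128)
    dropout_rate: float = 0.1
    learning_rate: float = 5e-5

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def source(self) -> str:
        return self.direction.split("_to_")[0]

    @property
    def target(self) -> str:
        return self.direction.split("_to_")[1]


class SynthesisModel:
    """U-Net translator wrapping the shared architecture machinery."""

    def __init__(self, config: SynthesisConfig, seed: int = 0):
        self.config = config
        self.net = Autoencoder(AutoencoderConfig(
            variant="UNET", input_shape=config.input_shape,
            n_blocks=config.n_blocks,
            channel_schedule=config.channel_schedule,
            dropout_rate=config.dropout_rate), seed=seed)

    def predict(self, volume: np.ndarray) -> np.ndarray:
        return self.net.forward(volume).reconstruction

    def save(self, directory: str):
        self.net.save(directory)
        import json
        with open(os.path.join(directory, "synthesis.json"), "w") as fh:
            json.dump({"direction": self.config.direction,
                       "learning_rate": self.config.learning_rate}, fh)

    @classmethod
    def load(cls, directory: str) -> "SynthesisModel":
        import json
        with open(os.path.join(directory, "synthesis.json")) as fh:
            meta = json.load(fh)
        net = Autoencoder.load(directory)
        cfg = SynthesisConfig(direction=meta["direction"],
                              input_shape=net.config.input_shape,
                              n_blocks=net.config.n_blocks,
                              channel_schedule=net.config.channel_schedule,
                              dropout_rate=net.config.dropout_rate,
                              learning_rate=meta["learning_rate"])
        model = cls.__new__(cls)
        model.config = cfg
        model.net = net
        return model


def build_synthesis_model(config: SynthesisConfig | None = None,
                          seed: int = 0) -> SynthesisModel:
    return SynthesisModel(config or SynthesisConfig(), seed=seed)


def train_synthesis(pairs: pd.DataFrame, config: SynthesisConfig,
                    train_config: TrainConfig | None = None,
                    source_data: np.ndarray | None = None,
                    target_data: np.ndarray | None = None,
                    loss_config: L.LossConfig | None = None,
                    seed: int = 0):
    """Train source->target synthesis on paired volumes.

    ``pairs`` needs columns patient_id, source_path, target_path (or
    pass preloaded (N,1,D,H,W) ``source_data``/``target_data`` aligned
    with its rows).  Patient-level 80/20 split; optimizes the SSIM loss
    between synthesized and true target.  Returns (model, history).
    """
    if len(pairs) == 0:
        raise ValueError("no training pairs")
    if pairs["patient_id"].duplicated().any():
        raise ValueError("duplicate patients in pairs manifest")
    tc = train_config or TrainConfig(learning_rate=config.learning_rate)
    model = build_synthesis_model(config, seed=seed)
    if source_data is None:
        source_data = np.stack([read_volume(p).data for p in pairs["source_path"]])[:, None]
    if target_data is None:
        target_data = np.stack([read_volume(p).data for p in pairs["target_path"]])[:, None]
    idx = pairs.reset_index(drop=True)
    idx["row"] = np.arange(len(idx))
    tr, va = split_scans(idx, tc.split_fraction, tc.seed)
    net, history = _train_pairs(model.net, source_data, target_data,
                                tr["row"].to_numpy(), va["row"].to_numpy(), tc,
                                loss_config or L.LossConfig())
    model.net = net
    return model, history


def _train_pairs(net, xs, ys, train_rows, val_rows, tc: TrainConfig,
                 lc: L.LossConfig):
    """Reuse the autoencoder trainer by wrapping paired supervision."""
    from . import nn
    from .training import EarlyStopper, _snapshot, _restore
    import time as _time

    opt = nn.Adam(net.named_parameters(), lr=tc.learning_rate)
    stopper = EarlyStopper(tc.patience, tc.min_delta)
    rng = np.random.default_rng(tc.seed)
    rows = []
    best = _snapshot(net)
    for epoch in range(tc.max_epochs):
        t0 = _time.time()
        net.set_training(True)
        order = rng.permutation(train_rows)
        tr_loss, nb = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            net.zero_grads()
            cache = net.forward_batch(xs[idx].astype(nn.DTYPE))
            recon = cache["recon"]
            B = len(idx)
            tr_loss += float(np.mean([1.0 - L.ssim_of(ys[i, 0].astype(np.float64),
                                                      recon[j, 0].astype(np.float64), lc)
                                      for j, i in enumerate(idx)]))
            drecon = np.stack([
                -L.ssim_grad_of(ys[i, 0].astype(np.float64),
                                recon[j, 0].astype(np.float64), lc) / B
                for j, i in enumerate(idx)])[:, None].astype(recon.dtype)
            net.backward_batch(cache, drecon)
            opt.step()
            nb += 1
        net.set_training(False)
        va_loss, nvb = 0.0, 0
        for start in range(0, len(val_rows), tc.batch_size):
            idx = val_rows[start:start + tc.batch_size]
            cache = net.forward_batch(xs[idx].astype(nn.DTYPE))
            va_loss += float(np.mean([1.0 - L.ssim_of(ys[i, 0].astype(np.float64),
                                                      cache["recon"][j, 0].astype(np.float64), lc)
                                      for j, i in enumerate(idx)]))
            nvb += 1
        rows.append({"epoch": epoch, "train_loss": tr_loss / max(nb, 1),
                     "val_loss": va_loss / max(nvb, 1),
                     "seconds": _time.time() - t0})
        improved = rows[-1]["val_loss"] <= stopper.best
        stop = stopper.update(epoch, rows[-1]["val_loss"])
        if improved or stopper.best_epoch == epoch:
            best = _snapshot(net)
        if stop:
            break
    _restore(net, best)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = int(stopper.best_epoch)
    return net, history


def synthesize(model: SynthesisModel, volume: Volume,
               direction: str | None = None) -> Volume:
    """Synthesize the target sequence from a preprocessed source volume."""
    direction = direction or model.config.direction
    if direction != model.config.direction:
        raise ValueError(f"model was trained for {model.config.direction}, "
                         f"not {direction}")
    if volume.sequence != model.config.source:
        raise ValueError(f"expected a {model.config.source} volume, got "
                         f"{volume.sequence}")
    data = model.predict(volume.data.astype(np.float64))
    return Volume(data=np.asarray(data, dtype=np.float64),
                  affine=volume.affine.copy(),
                  sequence=model.config.target, synthetic=True)


def augment_manifest(manifest: pd.DataFrame, model: SynthesisModel,
                     out_dir: str | None = None,
                     volume_loader=None, volume_store=None) -> pd.DataFrame:
    """Add synthetic target-sequence rows for patients lacking them.

    Real scans are never overwritten; synthetic files carry the
    ``_syn`` suffix and a ``synthetic`` manifest column.  In-memory
    pipelines can supply ``volume_loader(row)``/``volume_store(pid,
    volume)`` instead of disk I/O.
    """
    src, tgt = model.config.source, model.config.target
    if "synthetic" not in manifest.columns:
        manifest = manifest.assign(synthetic=False)
    new_rows = []
    for pid, grp in manifest.groupby("patient_id"):
        have = set(grp["sequence"])
        if tgt in have:
            continue
        if src not in have:
            continue
        row = grp[grp["sequence"] == src].iloc[0]
        if volume_loader is not None:
            vol = Volume(data=volume_loader(row), sequence=src)
        else:
            vol = read_volume(row["path"], sequence=src)
        syn = synthesize(model, vol)
        path = ""
        if volume_store is not None:
            volume_store(pid, syn)
        elif out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            path = os.path.join(out_dir, f"{pid}_{tgt}_syn.nii.gz")
            write_volume(syn, path)
        new_rows.append({"patient_id": pid, "cohort": row["cohort"],
                         "sequence": tgt, "path": path, "synthetic": True})
    if not new_rows:
        return manifest.reset_index(drop=True)
    return pd.concat([manifest, pd.DataFrame(new_rows)], ignore_index=True)
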