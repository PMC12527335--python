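"""Autoencoder training: cohort balancing, patient-level splits, the
SSIM(+beta*KLD) optimization loop with Adam and early stopping, and
checkpointing.

Defaults mirror the published protocol: batch size 14, Adam at 1e-4,
80/20 train/validation split, early stopping.  The convergence
criterion itself is unspecified there, so it is pinned here: stop when
validation loss has not improved by ``min_delta`` (1e-4) for
``patience`` (10) consecutive epochs, and return the weights of the
best validation epoch.

Splits are at PATIENT level — all of a patient's sequences stay on one
side — to prevent leakage between a patient's scans; all sequences are
pooled into a single training stream (one model serves every sequence).
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses as L
from . import nn
from .io_preprocess import read_volume
from .models import Autoencoder

# Development-corpus composition: a large healthy-volunteer cohort
# (UK Biobank, T1+FLAIR) balanced down to 800 cases against two glioma
# cohorts (UPenn-GBM 612 and UCSF-PDGM 495 cases, T1Gd+FLAIR).
REFERENCE_COHORTS = {
    "UKB": (19955, ("T1", "FLAIR")),
    "UPENN": (612, ("T1Gd", "FLAIR")),
    "UCSF": (495, ("T1Gd", "FLAIR")),
}
REFERENCE_CAPS = {"UKB": 800}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 14
    learning_rate: float = 1e-4
    optimizer: str = "ADAM"
    split_fraction: float = 0.8
    max_epochs: int = 50
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "ADAM":
            raise ValueError("only the ADAM optimizer is supported")


def balance_cohorts(manifest: pd.DataFrame, per_cohort_cap: dict,
                    seed: int = 0, allow_short: bool = False) -> pd.DataFrame:
    """Uniform per-cohort patient subsampling without replacement.

    All sequences of a retained patient are retained together.  A cap
    exceeding a cohort's size raises unless ``allow_short`` passes the
    cohort through unchanged.
    """
    rng = np.random.default_rng(seed)
    keep_parts = []
    for cohort, grp in manifest.groupby("cohort", sort=True):
        patients = np.sort(grp["patient_id"].unique())
        cap = per_cohort_cap.get(cohort)
        if cap is None or cap == len(patients):
            keep_parts.append(grp)
            continue
        if cap > len(patients):
            if not allow_short:
                raise ValueError(
                    f"cap {cap} exceeds cohort {cohort!r} size {len(patients)}")
            keep_parts.append(grp)
            continue
        chosen = set(rng.choice(patients, size=cap, replace=False))
        keep_parts.append(grp[grp["patient_id"].isin(chosen)])
    return pd.concat(keep_parts, ignore_index=True)


def reference_corpus_manifest() -> pd.DataFrame:
    """The development-corpus manifest TEMPLATE (paths empty): per-cohort
    patient counts and sequence availability, before balancing."""
    rows = []
    for cohort, (n, seqs) in REFERENCE_COHORTS.items():
        for i in range(n):
            for s in seqs:
                rows.append({"patient_id": f"{cohort}_{i:05d}", "cohort": cohort,
                             "sequence": s, "path": ""})
    return pd.DataFrame(rows)


def split_scans(manifest: pd.DataFrame, fraction: float = 0.8,
                seed: int = 0):
    """Patient-level train/validation split of a scan manifest."""
    patients = np.sort(manifest["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    n_train = int(round(fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = set(perm[:n_train])
    is_train = manifest["patient_id"].isin(train_ids)
    return (manifest[is_train].reset_index(drop=True),
            manifest[~is_train].reset_index(drop=True))


class EarlyStopper:
    """Stop when the monitored loss fails to improve by ``min_delta``
    for ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int = 10, min_delta: float = 1e-4):
        self.patience, self.min_delta = patience, min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, value: float) -> bool:
        if value < self.best - self.min_delta:
            self.best, self.best_epoch, self.stale = value, epoch, 0
        else:
            if value < self.best:
                self.best, self.best_epoch = value, epoch
            self.stale += 1
        return self.stale >= self.patience


def load_scan_array(manifest: pd.DataFrame) -> np.ndarray:
    """Stack the manifest's volumes into an (N, 1, D, H, W) float32 array."""
    vols = [read_volume(row.path, sequence=row.sequence).data
            for row in manifest.itertuples()]
    return np.stack(vols).astype(nn.DTYPE)[:, None]


def _batch_loss_and_grad(model, xb, loss_config, with_grad=True):
    cache = model.forward_batch(xb)
    recon = cache["recon"]
    B = xb.shape[0]
    ssim_l = float(np.mean([1.0 - L.ssim_of(xb[i, 0].astype(np.float64),
                                            recon[i, 0].astype(np.float64),
                                            loss_config)
                            for i in range(B)]))
    kld_l = 0.0
    dmu = dlv = None
    latent = cache["latent"]
    if latent is not None:
        mus, sigmas = latent.mu, latent.sigma
        kld_l = float(np.mean([L.kld_loss(mus[i], sigmas[i])
                               for i in range(B)]))
        if with_grad:
            gmu, gsig = L.kld_grads(mus, sigmas)
            dmu = loss_config.beta * gmu / B
            dlv = loss_config.beta * (gsig * 0.5 * sigmas) / B
    total = L.total_loss(ssim_l, kld_l, loss_config)
    if with_grad:
        drecon = np.stack([
            -L.ssim_grad_of(xb[i, 0].astype(np.float64),
                            recon[i, 0].astype(np.float64), loss_config) / B
            for i in range(B)])[:, None].astype(recon.dtype)
        model.backward_batch(cache, drecon, dmu, dlv)
    return total, ssim_l, kld_l


def _snapshot(model):
    return {p: layer.params[n].copy() for p, layer, n in model.named_parameters()}


def _restore(model, snap):
    for p, layer, n in model.named_parameters():
        layer.params[n] = snap[p].copy()


def train_autoencoder(model: Autoencoder, train_manifest: pd.DataFrame,
                      val_manifest: pd.DataFrame,
                      train_config: TrainConfig | None = None,
                      loss_config: L.LossConfig | None = None,
                      train_data: np.ndarray | None = None,
                      val_data: np.ndarray | None = None):
    """Optimize the reconstruction objective; return (model, history).

    ``train_data``/``val_data`` can carry preloaded (N,1,D,H,W) arrays
    to skip disk I/O; otherwise volumes are read from the manifests.
    Returns the model with the best-validation-epoch weights restored
    and a history DataFrame (per-epoch train/val loss and components).
    """
    tc = train_config or TrainConfig()
    lc = loss_config or L.LossConfig()
    if not model.config.is_variational:
        lc = L.LossConfig(beta=0.0, ssim_params=lc.ssim_params)
    xtr = train_data if train_data is not None else load_scan_array(train_manifest)
    xva = val_data if val_data is not None else load_scan_array(val_manifest)
    if len(xtr) == 0:
        raise ValueError("empty training set")
    if xtr.shape[2:] != model.config.input_shape:
        raise ValueError(f"scan shape {xtr.shape[2:]} does not match model "
                         f"input shape {model.config.input_shape}")
    opt = nn.Adam(model.named_parameters(), lr=tc.learning_rate)
    stopper = EarlyStopper(tc.patience, tc.min_delta)
    rng = np.random.default_rng(tc.seed)
    rows = []
    best_snap = _snapshot(model)
    for epoch in range(tc.max_epochs):
        t0 = time.time()
        model.set_training(True)
        order = rng.permutation(len(xtr))
        tr_tot = tr_ssim = tr_kld = 0.0
        nb = 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            model.zero_grads()
            tot, ssim_l, kld_l = _batch_loss_and_grad(model, xtr[idx], lc)
            opt.step()
            tr_tot += tot; tr_ssim += ssim_l; tr_kld += kld_l
            nb += 1
        model.set_training(False)
        va_tot = va_ssim = va_kld = 0.0
        nvb = 0
        for start in range(0, len(xva), tc.batch_size):
            tot, ssim_l, kld_l = _batch_loss_and_grad(
                model, xva[start:start + tc.batch_size], lc, with_grad=False)
            va_tot += tot; va_ssim += ssim_l; va_kld += kld_l
            nvb += 1
        rows.append({"epoch": epoch, "train_loss": tr_tot / nb,
                     "val_loss": va_tot / max(nvb, 1),
                     "train_ssim_loss": tr_ssim / nb,
                     "val_ssim_loss": va_ssim / max(nvb, 1),
                     "train_kld_loss": tr_kld / nb,
                     "val_kld_loss": va_kld / max(nvb, 1),
                     "seconds": time.time() - t0})
        improved = rows[-1]["val_loss"] <= stopper.best
        stop = stopper.update(epoch, rows[-1]["val_loss"])
        if improved or stopper.best_epoch == epoch:
            best_snap = _snapshot(model)
        if stop:
            break
    _restore(model, best_snap)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = int(stopper.best_epoch)
    return model, history


def save_checkpoint(model: Autoencoder, history: pd.DataFrame,
                    train_config: TrainConfig, directory: str):
    """config.json + weights + history.csv in one directory."""
    model.save(directory)
    history.to_csv(os.path.join(directory, "history.csv"), index=False)
    with open(os.path.join(directory, "train_config.json"), "w") as fh:
        json.dump({**train_config.__dict__,
                   "best_epoch": int(history.attrs.get("best_epoch", -1))}, fh)
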