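"""Shared fixtures: desk-scale training protocol and session-scoped
trained models, so the expensive phantom training runs happen once.

Desk protocol (used by every training-dependent test): 16**3 phantoms,
3 conv blocks with channel schedule (4, 8, 16), batch 8, Adam at 1e-3,
global-moment SSIM loss with stabilizers C1=0.01, C2=0.03 (appropriate
for the ~4-unit dynamic range of z-scored volumes).  See
docs/methods.md for why the tiny scale preserves the properties under
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neuroembed import losses as L
from neuroembed.models import AutoencoderConfig, build_model
from neuroembed.phantoms import CovariateModel, generate_preprocessed_cohort
from neuroembed.training import TrainConfig, train_autoencoder

GRID = (16, 16, 16)
N_BLOCKS = 3
SCHEDULE = (4, 8, 16)
TRAIN_LC = L.LossConfig(ssim_params=L.SSIMParams(C1=0.01, C2=0.03))


def desk_config(variant: str, **kw) -> AutoencoderConfig:
    return AutoencoderConfig(variant, input_shape=GRID, n_blocks=N_BLOCKS,
                             channel_schedule=SCHEDULE, **kw)


def desk_train_config(seed: int, epochs: int = 20) -> TrainConfig:
    return TrainConfig(batch_size=8, learning_rate=1e-3, max_epochs=epochs,
                       patience=epochs, seed=seed)


def pooled_manifest(n_scans: int) -> pd.DataFrame:
    return pd.DataFrame({"patient_id": [f"P{i}" for i in range(n_scans)],
                         "path": "", "sequence": ""})


def train_desk_model(variant: str, data: np.ndarray, seed: int,
                     epochs: int = 20):
    """Train one tiny autoencoder on a pooled (N,1,16,16,16) array with
    an 80/20 tail split; returns (model, history)."""
    n_tr = int(round(0.8 * len(data)))
    man = pooled_manifest(len(data))
    model = build_model(desk_config(variant), seed=seed)
    return train_autoencoder(model, man[:n_tr], man[n_tr:],
                             desk_train_config(seed, epochs), TRAIN_LC,
                             train_data=data[:n_tr], val_data=data[n_tr:])


@pytest.fixture(scope="session")
def eval_cohort():
    """200 fresh phantoms (T1 + FLAIR, preprocessed, in memory) with
    their clinical table — the standing evaluation set."""
    arrays, cohort = generate_preprocessed_cohort(
        200, CovariateModel(), sequences=("T1", "FLAIR"), seed=99,
        grid_shape=GRID)
    return arrays, cohort


@pytest.fixture(scope="session")
def trained_uae():
    """One U_AE trained on 40 phantoms (80 pooled T1+FLAIR scans)."""
    arrays, _ = generate_preprocessed_cohort(
        40, CovariateModel(), sequences=("T1", "FLAIR"), seed=7,
        grid_shape=GRID)
    pool = np.concatenate([arrays["T1"], arrays["FLAIR"]])
    model, history = train_desk_model("U_AE", pool, seed=7)
    return model, history


@pytest.fixture(scope="session")
def uae_embeddings(trained_uae, eval_cohort):
    """Embeddings (T1+FLAIR concatenated) of the evaluation cohort."""
    model, _ = trained_uae
    arrays, cohort = eval_cohort
    rows = [np.concatenate([model.forward(arrays["T1"][i, 0].astype(float)).features,
                            model.forward(arrays["FLAIR"][i, 0].astype(float)).features])
            for i in range(len(cohort.clinical))]
    return np.stack(rows), cohort.clinical


@pytest.fixture(scope="session")
def arch_comparison(eval_cohort):
    """The 5-seed matched UNET-vs-U_AE comparison: per seed, train both
    variants on the same 32-phantom T1 set, record the best validation
    SSIM and the out-of-fold lesion AUROC of each variant's embeddings
    on a 100-phantom subset of the evaluation cohort."""
    from neuroembed import evaluation as ev

    arrays, cohort = eval_cohort
    sub = slice(0, 100)
    y_lesion = cohort.clinical["lesion"].to_numpy()[sub]
    records = []
    for seed in range(5):
        tr_arrays, _ = generate_preprocessed_cohort(
            32, CovariateModel(), sequences=("T1",), seed=100 + seed,
            grid_shape=GRID)
        data = tr_arrays["T1"]
        for variant in ("UNET", "U_AE"):
            model, history = train_desk_model(variant, data, seed=seed)
            val_ssim = 1.0 - float(history["val_ssim_loss"].min())
            E = np.stack([model.forward(arrays["T1"][i, 0].astype(float)).features
                          for i in range(100)])
            res = ev.fit_predict_cv(E, y_lesion, "categorical", seed=seed)
            auroc = ev.score(res)["auroc"]
            records.append({"seed": seed, "variant": variant,
                            "val_ssim": val_ssim, "lesion_auroc": auroc})
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def synthesis_model():
    """T1->FLAIR translator trained on 64 phantom pairs."""
    from neuroembed.synthesis import SynthesisConfig, train_synthesis

    arrays, _ = generate_preprocessed_cohort(
        64, CovariateModel(), sequences=("T1", "FLAIR"), seed=21,
        grid_shape=GRID)
    pairs = pd.DataFrame({"patient_id": [f"P{i:05d}" for i in range(64)],
                          "source_path": "", "target_path": ""})
    sc = SynthesisConfig(direction="T1_to_FLAIR", input_shape=GRID,
                         n_blocks=N_BLOCKS, channel_schedule=SCHEDULE)
    model, history = train_synthesis(
        pairs, sc, desk_train_config(3, epochs=40),
        source_data=arrays["T1"], target_data=arrays["FLAIR"],
        loss_config=TRAIN_LC, seed=3)
    return model, history
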