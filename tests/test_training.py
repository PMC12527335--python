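"""Cohort balancing, splits, early stopping, the training loop, and
checkpointing."""

import numpy as np
import pandas as pd
import pytest

from conftest import TRAIN_LC, desk_config, desk_train_config, pooled_manifest
from neuroembed.models import Autoencoder, build_model
from neuroembed.phantoms import generate_preprocessed_cohort
from neuroembed.training import (EarlyStopper, TrainConfig, balance_cohorts,
                                 reference_corpus_manifest, split_scans,
                                 train_autoencoder)


def toy_manifest(cohort_sizes: dict, sequences=("T1", "FLAIR")):
    rows = []
    for cohort, n in cohort_sizes.items():
        for i in range(n):
            for s in sequences:
                rows.append({"patient_id": f"{cohort}{i}", "cohort": cohort,
                             "sequence": s, "path": ""})
    return pd.DataFrame(rows)


class TestBalanceCohorts:
    def test_cap_retains_exact_patient_count(self):
        man = toy_manifest({"A": 50, "B": 10})
        out = balance_cohorts(man, {"A": 20}, seed=0)
        assert out[out.cohort == "A"]["patient_id"].nunique() == 20
        assert out[out.cohort == "B"]["patient_id"].nunique() == 10
        # all sequences of retained patients kept together
        assert (out.groupby("patient_id").size() == 2).all()

    def test_cap_equal_size_identity(self):
        man = toy_manifest({"A": 5})
        out = balance_cohorts(man, {"A": 5}, seed=0)
        assert sorted(out["patient_id"]) == sorted(man["patient_id"])

    def test_determinism(self):
        man = toy_manifest({"A": 30})
        a = balance_cohorts(man, {"A": 10}, seed=4)
        b = balance_cohorts(man, {"A": 10}, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_cap_exceeding_raises_unless_allowed(self):
        man = toy_manifest({"A": 5})
        with pytest.raises(ValueError, match="cap"):
            balance_cohorts(man, {"A": 10}, seed=0)
        out = balance_cohorts(man, {"A": 10}, seed=0, allow_short=True)
        assert len(out) == len(man)

    def test_reference_corpus_scan_count(self):
        """Balancing the healthy cohort to 800 cases against the two
        glioma cohorts yields the 3,814-scan development corpus."""
        man = reference_corpus_manifest()
        balanced = balance_cohorts(man, {"UKB": 800}, seed=0)
        assert len(balanced) == 3814
        per = balanced.groupby("cohort").size()
        assert per["UKB"] == 1600 and per["UPENN"] == 1224 and per["UCSF"] == 990


class TestSplitScans:
    def test_eight_two_split(self):
        man = toy_manifest({"A": 10})
        tr, va = split_scans(man, 0.8, seed=0)
        assert tr["patient_id"].nunique() == 8
        assert va["patient_id"].nunique() == 2

    def test_partition_at_patient_level(self):
        man = toy_manifest({"A": 13})
        tr, va = split_scans(man, 0.8, seed=1)
        assert set(tr["patient_id"]) & set(va["patient_id"]) == set()
        joined = pd.concat([tr, va]).sort_values(["patient_id", "sequence"])
        assert len(joined) == len(man)

    def test_determinism(self):
        man = toy_manifest({"A": 9})
        a = split_scans(man, 0.8, seed=7)
        b = split_scans(man, 0.8, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_scans(toy_manifest({"A": 1}), 0.8, seed=0)


class TestEarlyStopper:
    def test_plateau_stops_with_patience(self):
        """Validation plateaus at epoch 5; patience 2 stops by epoch 7
        with best epoch 5."""
        series = [1.0, 0.8, 0.6, 0.5, 0.45, 0.40, 0.40, 0.40, 0.40]
        stopper = EarlyStopper(patience=2, min_delta=1e-4)
        stopped_at = None
        for epoch, v in enumerate(series):
            if stopper.update(epoch, v):
                stopped_at = epoch
                break
        assert stopped_at == 7
        assert stopper.best_epoch == 5

    def test_improving_series_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(e, 1.0 - 0.1 * e) for e in range(8))


class TestTrainAutoencoder:
    def test_training_reduces_validation_loss(self):
        """Tiny U_AE on 16 phantom scans: final validation SSIM loss
        below the initial one (seeded training-progress check)."""
        arrays, _ = generate_preprocessed_cohort(24, seed=31,
                                                 grid_shape=(16, 16, 16),
                                                 sequences=("T1",))
        data = arrays["T1"]
        model = build_model(desk_config("U_AE"), seed=0)
        man = pooled_manifest(24)
        model, hist = train_autoencoder(model, man[:19], man[19:],
                                        desk_train_config(0, epochs=12),
                                        TRAIN_LC, train_data=data[:19],
                                        val_data=data[19:])
        # the returned weights are the best validation epoch's
        assert hist["val_ssim_loss"].min() < hist["val_ssim_loss"].iloc[0]
        assert hist.attrs["best_epoch"] == hist["val_loss"].idxmin()

    def test_variational_history_has_both_components(self):
        arrays, _ = generate_preprocessed_cohort(8, seed=32,
                                                 grid_shape=(16, 16, 16),
                                                 sequences=("T1",))
        model = build_model(desk_config("U_VAE", latent_dim=16), seed=0)
        man = pooled_manifest(8)
        model, hist = train_autoencoder(model, man[:6], man[6:],
                                        desk_train_config(0, epochs=2),
                                        TRAIN_LC, train_data=arrays["T1"][:6],
                                        val_data=arrays["T1"][6:])
        assert {"train_ssim_loss", "train_kld_loss",
                "val_ssim_loss", "val_kld_loss"} <= set(hist.columns)
        assert (hist["train_kld_loss"] != 0).any()

    def test_empty_training_set_raises(self):
        model = build_model(desk_config("U_AE"), seed=0)
        empty = pooled_manifest(0)
        with pytest.raises(ValueError, match="empty"):
            train_autoencoder(model, empty, empty, TrainConfig(max_epochs=1),
                              train_data=np.zeros((0, 1, 16, 16, 16)),
                              val_data=np.zeros((0, 1, 16, 16, 16)))

    def test_shape_mismatch_raises(self):
        model = build_model(desk_config("U_AE"), seed=0)
        man = pooled_manifest(4)
        bad = np.zeros((4, 1, 8, 8, 8), dtype=np.float32)
        with pytest.raises(ValueError, match="shape"):
            train_autoencoder(model, man, man, TrainConfig(max_epochs=1),
                              train_data=bad, val_data=bad)


def test_checkpoint_roundtrip_after_training(tmp_path, trained_uae):
    """save -> load -> forward is bit-identical to the in-memory model."""
    model, history = trained_uae
    from neuroembed.training import save_checkpoint

    save_checkpoint(model, history, TrainConfig(), str(tmp_path / "ck"))
    loaded = Autoencoder.load(str(tmp_path / "ck"))
    x = np.random.default_rng(0).standard_normal((16, 16, 16))
    a, b = model.forward(x), loaded.forward(x)
    assert np.array_equal(a.features, b.features)
    assert np.array_equal(a.reconstruction, b.reconstruction)
    assert (tmp_path / "ck" / "history.csv").exists()
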