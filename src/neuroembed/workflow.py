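"""Configuration and staged pipeline drivers.

One strict, nested configuration object covers every stage; unknown
keys are rejected with their full key path so typos never silently
fall back to defaults.  Each stage function (``simulate``,
``preprocess_stage``, ``train_stage``, ``embed_stage``,
``synthesize_stage``, ``evaluate_stage``, ``end_to_end``) reads only
its own section plus the globals, writes under the output root, and
drops a machine-readable run record (config hash, seed, input/output
file hashes) next to its outputs.

The protocol constants (batch 14, lr 1e-4, beta 1e-4, k=140, 15%
missingness, 5 folds, 15 neighbors) are the defaults of the underlying
section objects; the size-like defaults here (cohort n, grid, channel
schedule) are desk-scale so an end-to-end run finishes on one CPU in
minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .embeddings import EmbeddingMatrix, checkpoint_sidecar, embed_cohort
from .io_preprocess import (PreprocessConfig, TemplateGrid, read_volume,
                            preprocess, write_volume)
from .losses import LossConfig
from .models import AutoencoderConfig, build_model, Autoencoder
from .phantoms import CovariateModel, generate_cohort
from .synthesis import SynthesisConfig, augment_manifest, train_synthesis
from .training import TrainConfig, save_checkpoint, split_scans, train_autoencoder


@dataclass(frozen=True)
class PhantomSection:
    n: int = 20
    grid_shape: tuple = (32, 32, 32)
    sequences: tuple = ("T1", "FLAIR")
    lesion_prevalence: float = 0.5
    hazard_coefficient: float = 0.15
    baseline_hazard: float = 0.02
    noise_sd: float = 0.02


@dataclass(frozen=True)
class PreprocessSection:
    grid_shape: tuple = (32, 32, 32)
    do_conform: bool = True
    do_zscore: bool = True
    closing_radius: int = 2
    brain_extract_cmd: str | None = None
    bias_correct_cmd: str | None = None
    register_cmd: str | None = None


@dataclass(frozen=True)
class ModelSection:
    variant: str = "U_AE"
    input_shape: tuple = (32, 32, 32)
    n_blocks: int = 3
    channel_schedule: tuple = (4, 8, 16)
    latent_dim: int | None = None
    dropout_rate: float = 0.0

    def to_autoencoder_config(self) -> AutoencoderConfig:
        return AutoencoderConfig(variant=self.variant,
                                 input_shape=self.input_shape,
                                 n_blocks=self.n_blocks,
                                 channel_schedule=self.channel_schedule,
                                 latent_dim=self.latent_dim,
                                 dropout_rate=self.dropout_rate)


@dataclass(frozen=True)
class EvaluationSection:
    folds: int = 5
    n_neighbors: int = 15
    missing_threshold: float = 0.15
    knn_k: int = 140
    rsf_trees: tuple = (100, 300)
    rsf_depth: tuple = (3, 6)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_root: str = "runs"
    phantoms: PhantomSection = field(default_factory=PhantomSection)
    preprocessing: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelSection = field(default_factory=ModelSection)
    training: TrainConfig = field(default_factory=lambda: TrainConfig(
        batch_size=14, max_epochs=15, patience=5))
    loss: LossConfig = field(default_factory=LossConfig)
    synthesis: SynthesisConfig = field(default_factory=lambda: SynthesisConfig(
        input_shape=(32, 32, 32), n_blocks=3, channel_schedule=(4, 8, 16)))
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)


_TUPLE_FIELDS = {"grid_shape", "sequences", "input_shape", "channel_schedule",
                 "rsf_trees", "rsf_depth"}


def _build_section(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise KeyError(f"unknown config key {path}.{key}" if path else
                           f"unknown config key {key}")
        ftype = names[key].type
        if dataclasses.is_dataclass(_SECTION_TYPES.get(key, None)) and isinstance(value, dict):
            value = _build_section(_SECTION_TYPES[key], value,
                                   f"{path}.{key}" if path else key)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTION_TYPES = {"phantoms": PhantomSection, "preprocessing": PreprocessSection,
                  "model": ModelSection, "training": TrainConfig,
                  "loss": LossConfig, "synthesis": SynthesisConfig,
                  "evaluation": EvaluationSection}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path or a nested dict (strict)."""
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    return _build_section(RunConfig, data, "")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_record(stage: str, config: RunConfig, inputs: list, outputs: list,
               directory: str) -> str:
    """Write a JSON record of a completed stage and return its path."""
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    record = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {p: _sha256(p) for p in inputs if os.path.isfile(p)},
        "outputs": {p: _sha256(p) for p in outputs if os.path.isfile(p)},
    }
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, f"record_{stage}.json")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate(config: RunConfig) -> dict:
    """Generate the phantom cohort on disk."""
    ph = config.phantoms
    out = os.path.join(config.out_root, "cohort")
    model = CovariateModel(lesion_prevalence=ph.lesion_prevalence,
                           hazard_coefficient=ph.hazard_coefficient,
                           baseline_hazard=ph.baseline_hazard,
                           noise_sd=ph.noise_sd)
    cohort = generate_cohort(ph.n, model, sequences=ph.sequences,
                             seed=config.seed, out_dir=out,
                             grid_shape=ph.grid_shape)
    outputs = [os.path.join(out, f) for f in
               ("manifest.csv", "clinical.csv", "truth.csv", "categories.json")]
    run_record("simulate", config, [], outputs, out)
    return {"cohort_dir": out, "manifest": cohort.manifest,
            "clinical": cohort.clinical}


def preprocess_stage(config: RunConfig, manifest: pd.DataFrame | None = None) -> dict:
    """Standardize every scan in the manifest onto the template grid."""
    pp = config.preprocessing
    out = os.path.join(config.out_root, "preprocessed")
    os.makedirs(out, exist_ok=True)
    if manifest is None:
        manifest = pd.read_csv(os.path.join(config.out_root, "cohort", "manifest.csv"))
    pconf = PreprocessConfig(grid=TemplateGrid(shape=pp.grid_shape),
                             do_conform=pp.do_conform, do_zscore=pp.do_zscore,
                             closing_radius=pp.closing_radius,
                             brain_extract_cmd=pp.brain_extract_cmd,
                             bias_correct_cmd=pp.bias_correct_cmd,
                             register_cmd=pp.register_cmd)
    rows, outputs = [], []
    for row in manifest.itertuples():
        vol = read_volume(row.path, sequence=row.sequence)
        proc, prov = preprocess(vol, pconf)
        path = os.path.join(out, os.path.basename(row.path))
        write_volume(proc, path)
        with open(path.replace(".nii.gz", "_prov.json"), "w") as fh:
            json.dump(prov, fh)
        rows.append({"patient_id": row.patient_id, "cohort": row.cohort,
                     "sequence": row.sequence, "path": path,
                     "synthetic": bool(getattr(row, "synthetic", False))})
        outputs.append(path)
    pre_manifest = pd.DataFrame(rows)
    mpath = os.path.join(out, "manifest.csv")
    pre_manifest.to_csv(mpath, index=False)
    run_record("preprocess", config, list(manifest["path"]), outputs + [mpath], out)
    return {"preprocessed_dir": out, "manifest": pre_manifest}


def train_stage(config: RunConfig, manifest: pd.DataFrame | None = None) -> dict:
    """Train the configured autoencoder on the preprocessed scans."""
    if manifest is None:
        manifest = pd.read_csv(os.path.join(config.out_root, "preprocessed",
                                            "manifest.csv"))
    model = build_model(config.model.to_autoencoder_config(), seed=config.seed)
    tc = dataclasses.replace(config.training, seed=config.seed)
    tr, va = split_scans(manifest, tc.split_fraction, tc.seed)
    model, history = train_autoencoder(model, tr, va, tc, config.loss)
    ckpt = os.path.join(config.out_root, "checkpoint")
    save_checkpoint(model, history, tc, ckpt)
    run_record("train", config, list(manifest["path"]),
               [os.path.join(ckpt, "weights.npz")], ckpt)
    return {"checkpoint_dir": ckpt, "model": model, "history": history}


def embed_stage(config: RunConfig, model: Autoencoder | None = None,
                manifest: pd.DataFrame | None = None) -> dict:
    """Extract per-sequence features and write the embedding matrix."""
    if model is None:
        model = Autoencoder.load(os.path.join(config.out_root, "checkpoint"))
    if manifest is None:
        manifest = pd.read_csv(os.path.join(config.out_root, "preprocessed",
                                            "manifest.csv"))
    matrix = embed_cohort(model, manifest, policy="strict")
    out = os.path.join(config.out_root, "embeddings")
    os.makedirs(out, exist_ok=True)
    path = os.path.join(out, "embeddings.csv")
    matrix.to_csv(path, sidecar=checkpoint_sidecar(model, "strict"))
    run_record("embed", config, list(manifest["path"]), [path], out)
    return {"embeddings_csv": path, "matrix": matrix}


def synthesize_stage(config: RunConfig, manifest: pd.DataFrame | None = None) -> dict:
    """Train the cross-modality model and add synthetic rows for
    patients missing the target sequence."""
    if manifest is None:
        manifest = pd.read_csv(os.path.join(config.out_root, "preprocessed",
                                            "manifest.csv"))
    sc = config.synthesis
    wide = manifest.pivot_table(index=["patient_id", "cohort"],
                                columns="sequence", values="path",
                                aggfunc="first").reset_index()
    pairs = wide.dropna(subset=[sc.source, sc.target])[
        ["patient_id", sc.source, sc.target]].rename(
            columns={sc.source: "source_path", sc.target: "target_path"})
    tc = dataclasses.replace(config.training, seed=config.seed,
                             learning_rate=sc.learning_rate)
    model, history = train_synthesis(pairs, sc, tc, seed=config.seed)
    out = os.path.join(config.out_root, "synthetic")
    augmented = augment_manifest(manifest, model, out_dir=out)
    mpath = os.path.join(out, "manifest.csv")
    os.makedirs(out, exist_ok=True)
    augmented.to_csv(mpath, index=False)
    ckpt = os.path.join(config.out_root, "synthesis_checkpoint")
    model.save(ckpt)
    run_record("synthesize", config, list(manifest["path"]), [mpath], out)
    return {"model": model, "history": history, "manifest": augmented,
            "manifest_csv": mpath}


def evaluate_stage(config: RunConfig, matrix: EmbeddingMatrix | None = None,
                   clinical: pd.DataFrame | None = None) -> dict:
    """Predict every typed clinical variable from the embeddings."""
    if matrix is None:
        matrix = EmbeddingMatrix.from_csv(
            os.path.join(config.out_root, "embeddings", "embeddings.csv"))
    if clinical is None:
        clinical = pd.read_csv(os.path.join(config.out_root, "cohort",
                                            "clinical.csv"))
    evc = config.evaluation
    clinical = clinical.set_index("patient_id").loc[matrix.patient_ids]
    X = matrix.values
    metrics_rows = []
    rsf_grid = {"n_estimators": list(evc.rsf_trees),
                "max_depth": list(evc.rsf_depth)}
    for var, task in (("age", "quantitative"), ("sex", "categorical"),
                      ("lesion", "categorical")):
        y = clinical[var]
        try:
            res = ev.fit_predict_cv(X, y.to_numpy(), task, folds=evc.folds,
                                    seed=config.seed, ids=matrix.patient_ids)
        except ValueError:
            continue  # degenerate target at tiny n (e.g. single class)
        for metric, value in ev.score(res).items():
            if metric == "roc_points":
                continue
            metrics_rows.append({"variable": var, "task": task,
                                 "metric": metric, "value": value})
    try:
        res = ev.fit_predict_cv(X, {"time": clinical["time"].to_numpy(),
                                    "event": clinical["event"].to_numpy()},
                                "survival", folds=evc.folds, seed=config.seed,
                                ids=matrix.patient_ids, rsf_grid=rsf_grid)
        for metric, value in ev.score(res).items():
            metrics_rows.append({"variable": "survival", "task": "survival",
                                 "metric": metric, "value": value})
    except ValueError:
        pass
    metrics = pd.DataFrame(metrics_rows)
    out = os.path.join(config.out_root, "evaluation")
    os.makedirs(out, exist_ok=True)
    mpath = os.path.join(out, "metrics.csv")
    metrics.to_csv(mpath, index=False)
    run_record("evaluate", config, [], [mpath], out)
    return {"metrics": metrics, "metrics_csv": mpath}


def end_to_end(config: RunConfig) -> dict:
    """simulate -> preprocess -> train -> embed -> evaluate."""
    sim = simulate(config)
    pre = preprocess_stage(config, sim["manifest"])
    trained = train_stage(config, pre["manifest"])
    emb = embed_stage(config, trained["model"], pre["manifest"])
    result = evaluate_stage(config, emb["matrix"], sim["clinical"])
    result.update(embeddings_csv=emb["embeddings_csv"],
                  history=trained["history"])
    return result
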