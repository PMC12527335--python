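"""Patient-level embedding construction.

Per-sequence features come from the trained autoencoder's bottleneck
(flattened activations for conventional variants; the latent mean mu —
never a sample — for variational ones).  A patient's embedding is the
concatenation of their per-sequence feature vectors in the canonical
order (T1, T1Gd, FLAIR), restricted to the sequences present.  Column
provenance ``<sequence>:<index>`` is kept end to end so any downstream
result can be traced to the sequence segment it came from.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preprocess import read_volume
from .models import Autoencoder, embedding_dim

CANONICAL_ORDER = ("T1", "T1Gd", "FLAIR")


@dataclass
class Embedding:
    patient_id: str
    segments: dict  # sequence -> 1D feature vector, canonical order
    synthetic_segments: tuple = ()

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.segments[s] for s in self.segments])


def extract_features(model: Autoencoder, volume: np.ndarray) -> np.ndarray:
    """Bottleneck feature vector of one preprocessed volume."""
    result = model.forward(np.asarray(volume))
    assert result.features.shape == (embedding_dim(model.config),)
    return result.features


def concat_patient(segments: dict, policy: str = "strict",
                   expected=None) -> Embedding:
    """Concatenate per-sequence features for one patient.

    ``strict`` errors on any expected-but-missing sequence; by default
    the expectation is the full canonical set restricted to nothing, so
    pass ``expected`` explicitly for strict use.  ``available_only``
    concatenates whatever exists and records the availability.
    """
    if policy not in ("strict", "available_only"):
        raise ValueError(f"unknown policy {policy!r}")
    if not segments:
        raise ValueError("no segments to concatenate")
    for s in segments:
        if s not in CANONICAL_ORDER:
            raise ValueError(f"unknown sequence label {s!r}")
    if policy == "strict":
        expected = tuple(expected) if expected is not None else CANONICAL_ORDER
        missing = [s for s in expected if s not in segments]
        if missing:
            raise ValueError(f"missing expected sequence(s): {', '.join(missing)}")
    ordered = {s: np.asarray(segments[s], dtype=np.float64).ravel()
               for s in CANONICAL_ORDER if s in segments}
    return Embedding(patient_id="", segments=ordered)


@dataclass
class EmbeddingMatrix:
    """Patients x features, with (sequence, index) column provenance."""

    values: np.ndarray
    patient_ids: list
    columns: list  # "<sequence>:<index>" strings
    synthetic_flags: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def to_csv(self, path: str, sidecar: dict | None = None):
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            with open(path + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "EmbeddingMatrix":
        df = pd.read_csv(path)
        return cls(values=df.drop(columns=["patient_id"]).to_numpy(np.float64),
                   patient_ids=list(df["patient_id"]),
                   columns=[c for c in df.columns if c != "patient_id"])


def embed_cohort(model: Autoencoder, manifest: pd.DataFrame,
                 policy: str = "strict",
                 expected_sequences=None,
                 volume_loader=None) -> EmbeddingMatrix:
    """One embedding row per patient, rows ordered by patient id.

    ``volume_loader(row) -> 3D array`` can override disk reads (used by
    tests and the in-memory pipeline).  Synthetic scans contribute
    features like real ones but are flagged in ``synthetic_flags``.
    """
    loader = volume_loader or (lambda row: read_volume(row.path, sequence=row.sequence).data)
    if expected_sequences is None:
        expected_sequences = tuple(s for s in CANONICAL_ORDER
                                   if s in set(manifest["sequence"]))
    feats: dict[str, dict] = {}
    synth: dict[str, dict] = {}
    for row in manifest.sort_values(["patient_id", "sequence"]).itertuples():
        feats.setdefault(row.patient_id, {})[row.sequence] = \
            extract_features(model, loader(row))
        synth.setdefault(row.patient_id, {})[row.sequence] = \
            bool(getattr(row, "synthetic", False))
    pids = sorted(feats)
    rows, flag_rows = [], []
    for pid in pids:
        emb = concat_patient(feats[pid], policy=policy, expected=expected_sequences)
        rows.append(emb.vector)
        flag_rows.append({s: synth[pid].get(s) for s in emb.segments})
    values = np.stack(rows)
    first = feats[pids[0]]
    columns = [f"{s}:{i}" for s in CANONICAL_ORDER if s in first
               for i in range(len(first[s]))]
    return EmbeddingMatrix(values=values, patient_ids=pids, columns=columns,
                           synthetic_flags=pd.DataFrame(flag_rows, index=pids))


def checkpoint_sidecar(model: Autoencoder, policy: str) -> dict:
    """Provenance sidecar for an embedding CSV."""
    weights = np.concatenate([layer.params[n].ravel()
                              for _, layer, n in model.named_parameters()])
    digest = hashlib.sha256(weights.astype(np.float32).tobytes()).hexdigest()
    return {"model_config": model.config.to_dict(), "policy": policy,
            "weights_sha256": digest,
            "canonical_order": list(CANONICAL_ORDER)}
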