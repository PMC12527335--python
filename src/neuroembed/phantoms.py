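"""Seeded multi-sequence 3D brain-phantom generator.

Stands in for the multi-institutional MRI cohorts the embedding
workflow was designed for.  Geometry is analytic — nested ellipsoids
(brain, gray-matter shell, ventricular CSF) plus an optional spherical
lesion — which is fast, fully parameterized, and plants recoverable
covariate-linked signal without attempting realistic cortical folding
or MR physics.

Tissue classes are {background=0, CSF=1, gray=2, white=3, lesion=4}.
Intensities come from a fixed per-(tissue, sequence) mean table chosen
so the contrast ordering matches clinical convention: CSF is dark on
T1 and suppressed on FLAIR, lesions are hyperintense relative to white
matter on FLAIR, and T1Gd lesions show a contrast-enhancing ring around
a darker core.  On top of the means sit additive Gaussian noise
(``noise_sd``) and a multiplicative global ``site_bias`` emulating
site/protocol intensity effects.

Cohort generation links morphology to covariates (age -> ventricle
size, sex -> global brain scale, Bernoulli lesion prevalence) and draws
exponential survival times whose log-hazard is
``log(baseline_hazard) + hazard_coefficient * lesion_volume`` with an
independent uniform censoring process.  Reproducibility: one seed per
cohort, split per patient by counter (``SeedSequence(seed).spawn``), so
a patient's phantom is identical regardless of generation order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEQUENCES = ("T1", "T1Gd", "FLAIR")
TISSUES = {"background": 0, "CSF": 1, "gray": 2, "white": 3, "lesion": 4}

# mean intensity per tissue class, per sequence (arbitrary units in [0, 1])
INTENSITY_TABLE = {
    "T1":    {0: 0.0, 1: 0.10, 2: 0.50, 3: 0.70, 4: 0.40},
    "T1Gd":  {0: 0.0, 1: 0.10, 2: 0.50, 3: 0.70, 4: 0.30},  # 4 = lesion core
    "FLAIR": {0: 0.0, 1: 0.15, 2: 0.50, 3: 0.45, 4: 0.90},
}
T1GD_RIM_INTENSITY = 0.90  # contrast-enhancing ring on T1Gd


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for a single patient's phantom."""

    grid_shape: tuple = (64, 64, 64)
    ventricle_scale: float = 1.0
    brain_scale: float = 1.0
    lesion_present: bool = False
    lesion_radius: float = 0.0
    site_bias: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be a 3-tuple with entries >= 16")
        if self.ventricle_scale <= 0 or self.brain_scale <= 0:
            raise ValueError("ventricle_scale and brain_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_present != (self.lesion_radius > 0):
            raise ValueError("lesion_radius must be > 0 iff lesion_present")


@dataclass(frozen=True)
class CovariateModel:
    """How covariates map to phantom morphology and survival.

    ``age_to_ventricle`` is an affine monotone map (years -> ventricle
    scale); ``sex_to_brain`` scales global brain size by sex; lesion
    volume (as a fraction of grid voxels, in permille) multiplies the
    log-hazard of the exponential survival model.
    """

    age_range: tuple = (45.0, 80.0)
    ventricle_at_min_age: float = 0.85
    ventricle_per_year: float = 0.012
    sex_to_brain: dict = field(default_factory=lambda: {"F": 0.92, "M": 1.05})
    lesion_prevalence: float = 0.5
    lesion_radius_range: tuple = (0.10, 0.18)  # fraction of min grid dim
    hazard_coefficient: float = 0.15  # per permille lesion volume
    baseline_hazard: float = 0.02  # events per month
    censor_horizon: float = 120.0  # months of administrative follow-up
    noise_sd: float = 0.02
    site_bias_sd: float = 0.05  # sd of log site bias

    def __post_init__(self):
        if not 0.0 <= self.lesion_prevalence <= 1.0:
            raise ValueError("lesion_prevalence must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    def age_to_ventricle(self, age: float) -> float:
        return self.ventricle_at_min_age + self.ventricle_per_year * (age - self.age_range[0])


@dataclass
class PhantomCohort:
    """Generated cohort: scan manifest, clinical table, and the ground
    truth generative parameters per patient."""

    manifest: pd.DataFrame   # patient_id, cohort, sequence, path
    clinical: pd.DataFrame   # patient_id, age, sex, lesion, time, event
    truth: pd.DataFrame      # per-patient generative parameters
    category_map: dict       # variable -> {category, type}


def _ellipsoid_mask(shape, center, semiaxes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec, sequences=("T1", "FLAIR"),
                     seed: int = 0):
    """Render one phantom: dict of sequence -> intensity volume, plus the
    shared tissue label map.

    All sequences share geometry; only the intensity table and noise
    realization differ.  Raises if the lesion cannot fit inside the
    white-matter compartment.
    """
    for s in sequences:
        if s not in SEQUENCES:
            raise ValueError(f"unknown sequence label {s!r}; expected subset of {SEQUENCES}")
    labels = render_label_map(spec)
    rng = np.random.default_rng(seed)
    volumes = {}
    for s in sequences:
        table = INTENSITY_TABLE[s]
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        for tissue, mean in table.items():
            vol[labels == tissue] = mean
        # internal code 5 = lesion rim: contrast-enhancing on T1Gd,
        # plain lesion tissue on every other sequence
        if spec.lesion_present:
            vol[labels == 5] = (T1GD_RIM_INTENSITY if s == "T1Gd"
                                else table[TISSUES["lesion"]])
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
        vol *= spec.site_bias
        volumes[s] = vol
    # rim voxels (internal code 5) are lesion tissue in the public map
    labels = np.where(labels == 5, TISSUES["lesion"], labels)
    return volumes, labels


def render_label_map(spec: PhantomSpec) -> np.ndarray:
    """Tissue label map only (no intensities, no noise); internal code 5
    marks the T1Gd-enhancing lesion rim, collapsed to 'lesion' by
    :func:`generate_phantom`."""
    shape = np.array(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    brain_ax = 0.42 * shape * spec.brain_scale
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    brain = _ellipsoid_mask(spec.grid_shape, center, brain_ax)
    labels[brain] = TISSUES["gray"]
    white = _ellipsoid_mask(spec.grid_shape, center, 0.80 * brain_ax)
    labels[white] = TISSUES["white"]
    # two lateral ventricles, offset along the second axis
    vent_ax = 0.16 * shape * spec.ventricle_scale
    for sign in (-1.0, 1.0):
        c = center + np.array([0.0, sign * 0.18 * shape[1] * spec.brain_scale, 0.0])
        vent = _ellipsoid_mask(spec.grid_shape, c, vent_ax)
        labels[vent & white] = TISSUES["CSF"]
    if spec.lesion_present:
        r = float(spec.lesion_radius)
        lesion_center = center + np.array([0.45 * brain_ax[0], 0.0, 0.0])
        # lesion must fit inside the brain ellipsoid
        margin = ((lesion_center - center) / brain_ax) ** 2
        if margin.sum() ** 0.5 + r / brain_ax.min() > 1.0:
            raise ValueError(
                f"lesion_radius {r} at offset {lesion_center - center} does not "
                f"fit inside the brain ellipsoid (semi-axes {brain_ax})")
        lesion = _ellipsoid_mask(spec.grid_shape, lesion_center, (r, r, r))
        labels[lesion & (labels > 0)] = TISSUES["lesion"]
        core = _ellipsoid_mask(spec.grid_shape, lesion_center,
                               (max(r - 1.5, 0.5),) * 3)
        rim = lesion & ~core & (labels == TISSUES["lesion"])
        labels[rim] = 5
    return labels


def _spawn_patient_seeds(seed: int, n: int):
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(np.random.default_rng(c).integers(0, 2**31 - 1)) for c in children]


def generate_cohort(n: int, model: CovariateModel | None = None,
                    sequences=("T1", "FLAIR"), seed: int = 0,
                    out_dir: str | None = None,
                    grid_shape=(64, 64, 64), cohort_name: str = "PHANTOM",
                    render: bool = True) -> PhantomCohort:
    """Generate an ``n``-patient phantom cohort.

    Writes one NIfTI per (patient, sequence) under ``out_dir`` when
    rendering; ``render=False`` skips intensity rendering and disk I/O
    (label-map geometry and the clinical table are still exact), which
    is what the large-n statistical checks use.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or CovariateModel()
    if render:
        if out_dir is None:
            raise ValueError("out_dir is required when render=True")
        os.makedirs(out_dir, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise OSError(f"out_dir {out_dir!r} is not writable")
    from .io_preprocess import Volume, write_volume

    patient_seeds = _spawn_patient_seeds(seed, n)
    manifest_rows, clinical_rows, truth_rows = [], [], []
    for i in range(n):
        pid = f"P{i:05d}"
        prng = np.random.default_rng(patient_seeds[i])
        age = float(prng.uniform(*model.age_range))
        sex = "M" if prng.random() < 0.5 else "F"
        lesion = bool(prng.random() < model.lesion_prevalence)
        radius = 0.0
        if lesion:
            lo, hi = model.lesion_radius_range
            radius = float(prng.uniform(lo, hi) * min(grid_shape))
        spec = PhantomSpec(
            grid_shape=grid_shape,
            ventricle_scale=model.age_to_ventricle(age),
            brain_scale=model.sex_to_brain[sex],
            lesion_present=lesion,
            lesion_radius=radius,
            site_bias=float(np.exp(prng.normal(0.0, model.site_bias_sd))),
            noise_sd=model.noise_sd,
        )
        labels = render_label_map(spec)
        lesion_voxels = int(np.sum((labels == TISSUES["lesion"]) | (labels == 5)))
        lesion_permille = 1000.0 * lesion_voxels / labels.size
        log_hazard = np.log(model.baseline_hazard) + model.hazard_coefficient * lesion_permille
        t_event = float(prng.exponential(1.0 / np.exp(log_hazard)))
        t_censor = float(prng.uniform(0.0, model.censor_horizon))
        time = min(t_event, t_censor)
        event = int(t_event <= t_censor)
        if render:
            vol_seed = int(prng.integers(0, 2**31 - 1))
            volumes, _ = generate_phantom(spec, sequences, seed=vol_seed)
            for s in sequences:
                path = os.path.join(out_dir, f"{pid}_{s}.nii.gz")
                write_volume(Volume(data=volumes[s], affine=np.eye(4), sequence=s), path)
                manifest_rows.append({"patient_id": pid, "cohort": cohort_name,
                                      "sequence": s, "path": path})
        else:
            for s in sequences:
                manifest_rows.append({"patient_id": pid, "cohort": cohort_name,
                                      "sequence": s, "path": ""})
        clinical_rows.append({"patient_id": pid, "age": age, "sex": sex,
                              "lesion": int(lesion), "time": max(time, 1e-6),
                              "event": event})
        truth_rows.append({"patient_id": pid, "seed": patient_seeds[i],
                           "ventricle_scale": spec.ventricle_scale,
                           "brain_scale": spec.brain_scale,
                           "lesion_present": int(lesion),
                           "lesion_radius": radius,
                           "lesion_permille": lesion_permille,
                           "site_bias": spec.site_bias})
    category_map = {
        "age": {"category": "demographics", "type": "quantitative"},
        "sex": {"category": "demographics", "type": "categorical"},
        "lesion": {"category": "pathology", "type": "categorical"},
        "survival": {"category": "outcome", "type": "survival",
                     "time": "time", "event": "event"},
    }
    cohort = PhantomCohort(manifest=pd.DataFrame(manifest_rows),
                           clinical=pd.DataFrame(clinical_rows),
                           truth=pd.DataFrame(truth_rows),
                           category_map=category_map)
    if render:
        import json
        cohort.manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        cohort.clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
        cohort.truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
        with open(os.path.join(out_dir, "categories.json"), "w") as fh:
            json.dump(category_map, fh, indent=1)
    return cohort


def generate_preprocessed_cohort(n: int, model: CovariateModel | None = None,
                                 sequences=("T1", "FLAIR"), seed: int = 0,
                                 grid_shape=(16, 16, 16),
                                 closing_radius: int = 1):
    """In-memory cohort of already-standardized volumes.

    Convenience path for desk-scale work: renders each phantom, masks
    and z-scores it (no conforming — the phantoms are born on a common
    grid and co-registered by construction), and returns
    ``({sequence: (n, 1, *grid) float32 array}, PhantomCohort)``
    without touching disk.  Deterministic in (model, seed).
    """
    from . import nn
    from .io_preprocess import Volume, extract_brain_mask, zscore_normalize

    model = model or CovariateModel()
    cohort = generate_cohort(n, model, sequences=sequences, seed=seed,
                             render=False, grid_shape=grid_shape)
    arrays = {s: [] for s in sequences}
    for row in cohort.truth.itertuples():
        spec = PhantomSpec(grid_shape=grid_shape,
                           ventricle_scale=row.ventricle_scale,
                           brain_scale=row.brain_scale,
                           lesion_present=bool(row.lesion_present),
                           lesion_radius=row.lesion_radius,
                           site_bias=row.site_bias, noise_sd=model.noise_sd)
        rng = np.random.default_rng(int(row.seed))
        vol_seed = int(rng.integers(0, 2**31 - 1))
        volumes, _ = generate_phantom(spec, sequences, seed=vol_seed)
        for s in sequences:
            v = Volume(data=volumes[s], sequence=s)
            mask = extract_brain_mask(v, closing_radius=closing_radius)
            arrays[s].append(zscore_normalize(v, mask).data)
    stacked = {s: np.stack(a).astype(nn.DTYPE)[:, None]
               for s, a in arrays.items()}
    return stacked, cohort
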