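"""NIfTI I/O and the native standardization steps of the preprocessing
pipeline.

Implemented natively: Otsu-threshold brain-mask extraction (largest
connected component, morphological closing), within-mask z-score
normalization, and rigid conforming to a fixed template grid (default
[182, 218, 160] at 1 mm — the MNI-152-shaped grid) by integer-voxel
center-of-mass translation plus resampling.  The heavyweight external
stages of a production pipeline (atlas-based brain extraction, N4 bias
correction, deformable template registration) are deliberately NOT
reimplemented: they are exposed as optional external-command hooks
(``brain_extract_cmd`` etc., command templates with ``{in}``/``{out}``
placeholders) and skipped by default so the pipeline runs without any
external binaries.

Conventions asserted throughout: voxel indices 0-based, axes (X, Y, Z),
world frame RAS via the NIfTI affine.
"""

from __future__ import annotations

import json
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

SEQUENCE_LABELS = ("T1", "T1Gd", "FLAIR", "other")


@dataclass
class Volume:
    """A 3D scalar grid with voxel-to-world affine and sequence label."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    sequence: str = "other"
    synthetic: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        n_nan = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_nan:
            raise ValueError(f"volume contains {n_nan} non-finite voxels")

    @property
    def spacing(self) -> tuple:
        return tuple(float(s) for s in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass(frozen=True)
class TemplateGrid:
    """Target grid for conforming; default matches the 1-mm template
    space with shape [182, 218, 160] (> 5 million voxels)."""

    shape: tuple = (182, 218, 160)
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class BrainMask:
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("brain mask is empty")


def read_volume(path: str, sequence: str | None = None) -> Volume:
    """Read a NIfTI-1 volume (.nii / .nii.gz)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI payload, got {data.ndim}D in {path}")
    descrip = ""
    try:
        descrip = img.header["descrip"].item().decode("ascii", "ignore")
    except Exception:
        pass
    if sequence is None:
        sequence = "other"
        for tok in descrip.split(";"):
            if tok.startswith("seq="):
                sequence = tok[4:]
    return Volume(data=np.asarray(data, dtype=np.float64), affine=img.affine,
                  sequence=sequence, synthetic="synthetic=true" in descrip)


def write_volume(volume: Volume, path: str) -> None:
    """Write a NIfTI-1 volume, preserving affine and labels in the header."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    tags = [f"seq={volume.sequence}"]
    if volume.synthetic:
        tags.append("synthetic=true")
    img.header["descrip"] = ";".join(tags).encode("ascii")[:79]
    nib.save(img, path)


def _foreground(data: np.ndarray) -> np.ndarray:
    """Global-threshold foreground.

    Volumes that have already been background-zeroed (a large class of
    exact zeros, as produced by :func:`zscore_normalize`) reuse their
    zero set as background — Otsu on a z-scored volume would otherwise
    cut through the brain.  Everything else gets an Otsu threshold.
    """
    zeros = data == 0.0
    if zeros.mean() > 0.2 and not zeros.all():
        return ~zeros
    return data > threshold_otsu(data)


def extract_brain_mask(volume: Volume, closing_radius: int = 3) -> BrainMask:
    """Threshold-based brain-mask stand-in.

    Otsu threshold on the intensity histogram (zero-set reuse for
    already-masked input), morphological closing with a ball of the
    given radius, then the largest connected component with holes
    filled.  A stand-in for atlas-based skull stripping — adequate
    because phantoms have no skull.
    """
    data = volume.data
    if float(data.max()) == float(data.min()):
        raise ValueError("no foreground: volume intensity is constant")
    fg = _foreground(data)
    if not fg.any():
        raise ValueError("no foreground above the Otsu threshold")
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    lab, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(lab == keep)
    return BrainMask(mask=mask)


def zscore_normalize(volume: Volume, mask: BrainMask) -> Volume:
    """Z-score intensities within the brain mask; background set to 0.

    Uses the population standard deviation; raises if the within-mask
    variance is zero (no silent pass-through).
    """
    if mask.mask.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume")
    vals = volume.data[mask.mask]
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero intensity variance within mask; cannot z-score")
    out = np.zeros_like(volume.data, dtype=np.float64)
    out[mask.mask] = (vals - vals.mean()) / sd
    return Volume(data=out, affine=volume.affine.copy(),
                  sequence=volume.sequence, synthetic=volume.synthetic)


def _center_of_mass(data: np.ndarray) -> np.ndarray:
    """Geometric centroid of the foreground (robust to z-scoring)."""
    if float(data.max()) == float(data.min()):
        return (np.array(data.shape, dtype=float) - 1) / 2
    fg = _foreground(data)
    if not fg.any():
        return (np.array(data.shape, dtype=float) - 1) / 2
    return np.array(ndimage.center_of_mass(fg))


def conform_to_grid(volume: Volume, grid: TemplateGrid | None = None,
                    mask: BrainMask | None = None):
    """Rigidly place the volume on the template grid.

    Stand-in for deformable template registration: scales for voxel
    spacing and translates the foreground centroid (of ``mask`` when
    given, else a global-threshold foreground) to the grid center, with
    the translation rounded to whole voxels so integer shifts are exact
    under trilinear resampling and conforming is idempotent.  When a
    mask is supplied it is resampled with the same transform (nearest
    neighbour) and the pair is returned.
    """
    grid = grid or TemplateGrid()
    scale = np.array(volume.spacing) / np.array(grid.spacing)
    if mask is not None:
        com_in = np.array(ndimage.center_of_mass(mask.mask))
    else:
        com_in = _center_of_mass(volume.data)
    center_out = (np.array(grid.shape, dtype=float) - 1) / 2
    # output voxel -> input voxel: x_in = x_out/scale + offset
    matrix = np.diag(1.0 / scale)
    offset = np.round(com_in - center_out / scale)
    out = ndimage.affine_transform(volume.data, matrix, offset=offset,
                                   output_shape=grid.shape, order=1,
                                   mode="constant", cval=0.0)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = -center_out * np.array(grid.spacing)
    conformed = Volume(data=out, affine=affine, sequence=volume.sequence,
                       synthetic=volume.synthetic)
    if mask is None:
        return conformed
    mask_out = ndimage.affine_transform(mask.mask.astype(np.uint8), matrix,
                                        offset=offset, output_shape=grid.shape,
                                        order=0, mode="constant", cval=0)
    return conformed, BrainMask(mask=mask_out.astype(bool))


@dataclass
class PreprocessConfig:
    """Which standardization steps run, and optional external hooks."""

    do_mask: bool = True
    do_conform: bool = True
    do_zscore: bool = True
    grid: TemplateGrid = field(default_factory=TemplateGrid)
    closing_radius: int = 3
    brain_extract_cmd: str | None = None
    bias_correct_cmd: str | None = None
    register_cmd: str | None = None


def _run_hook(name: str, template: str, volume: Volume) -> Volume:
    binary = template.split()[0]
    if shutil.which(binary) is None:
        raise RuntimeError(f"external hook {name!r} requires missing binary {binary!r}")
    with tempfile.TemporaryDirectory() as tmp:
        pin = os.path.join(tmp, "in.nii.gz")
        pout = os.path.join(tmp, "out.nii.gz")
        write_volume(volume, pin)
        cmd = template.format(**{"in": pin, "out": pout})
        subprocess.run(cmd, shell=True, check=True)
        return read_volume(pout, sequence=volume.sequence)


def preprocess(volume: Volume, config: PreprocessConfig | None = None):
    """Standardize one volume: mask -> (hooks) -> conform -> z-score.

    Returns ``(volume, provenance)`` where provenance lists the applied
    steps and their parameters (serializable to JSON).
    """
    config = config or PreprocessConfig()
    steps = []
    mask = None
    if config.do_mask or config.do_zscore:
        mask = extract_brain_mask(volume, config.closing_radius)
        steps.append({"step": "mask", "method": "otsu+closing",
                      "closing_radius": config.closing_radius,
                      "n_voxels": int(mask.mask.sum())})
    for hook in ("brain_extract_cmd", "bias_correct_cmd", "register_cmd"):
        template = getattr(config, hook)
        if template:
            volume = _run_hook(hook, template, volume)
            steps.append({"step": hook, "cmd": template})
    if config.do_conform:
        if mask is not None:
            volume, mask = conform_to_grid(volume, config.grid, mask)
        else:
            volume = conform_to_grid(volume, config.grid)
        steps.append({"step": "conform", "shape": list(config.grid.shape),
                      "spacing": list(config.grid.spacing)})
    if config.do_zscore:
        volume = zscore_normalize(volume, mask)
        steps.append({"step": "zscore", "scope": "within-mask"})
    provenance = {"sequence": volume.sequence, "synthetic": volume.synthetic,
                  "steps": steps}
    return volume, provenance


def write_provenance(provenance: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=1)
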