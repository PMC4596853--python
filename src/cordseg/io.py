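"""Volume containers, NIfTI I/O, gradient image, and template-database persistence.

The segmentation operates on two grids of numbers: the raw MR intensities and
the voxelwise gradient magnitude ("gradient image"), whose ridges trace the
cord/CSF interface. Both live in :class:`Volume`, which carries the anisotropic
voxel spacing (mm) and the voxel-index -> world-mm affine so that all geometry
downstream is done in physical units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .errors import FormatError

log = logging.getLogger(__name__)

TEMPLATE_DB_FORMAT_VERSION = 1


@dataclass
class Volume:
    """A 3-D scalar grid with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (intensities or gradient magnitudes).
    spacing : ndarray, shape (3,)
        Voxel edge lengths in mm, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm homogeneous map (NIfTI convention).
    """

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected a 3-D volume, got {self.data.ndim}-D data"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise FormatError("spacing must be three strictly positive values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine
        )


@dataclass
class Mask(Volume):
    """A binary :class:`Volume` (uint8 values in {0, 1})."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            if vals.size <= 2:
                # e.g. {0, 255} label exports: normalize with a warning
                warnings.warn(
                    f"mask values {vals.tolist()} normalized to {{0,1}}",
                    stacklevel=3,
                )
                self.data = (self.data > 0)
            else:
                raise FormatError(
                    f"mask is not binary (found {vals.size} distinct values)"
                )
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3-D NIfTI volume, got {data.ndim}-D"
        )
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing, np.asarray(img.affine, dtype=float)


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI volume."""
    data, spacing, affine = _load_nifti(path)
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing,
                  affine=affine)


def read_mask(path: str | Path) -> Mask:
    """Read a 3-D NIfTI label volume as a binary mask ({0,255} tolerated)."""
    data, spacing, affine = _load_nifti(path)
    return Mask(data=data, spacing=spacing, affine=affine)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.data, dtype=np.uint8), mask.affine)
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))


def gradient_magnitude(vol: Volume, presmooth_sigma_mm: float = 0.0,
                       in_plane: bool = False) -> Volume:
    """Voxelwise magnitude of the spatial intensity gradient.

    Per-axis central differences (one-sided at the borders) divided by the
    per-axis spacing, then the Euclidean norm across axes — so anisotropic
    voxels are measured in mm^-1 units consistently.

    Parameters
    ----------
    presmooth_sigma_mm : float
        Optional Gaussian pre-filter (mm); 0 disables it (default).
    in_plane : bool
        If True, only the two in-plane (axial x/y) derivatives enter the norm.
    """
    if min(vol.shape) < 2:
        raise FormatError("gradient needs at least 2 voxels per axis")
    data = np.asarray(vol.data, dtype=np.float64)
    if presmooth_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(data, sigma=presmooth_sigma_mm / vol.spacing)
    axes = (0, 1) if in_plane else (0, 1, 2)
    grads = [np.gradient(data, vol.spacing[a], axis=a) for a in axes]
    mag = np.sqrt(np.sum([g * g for g in grads], axis=0))
    return Volume(data=mag.astype(np.float32), spacing=vol.spacing.copy(),
                  affine=vol.affine.copy())


def save_template_db(db, path: str | Path) -> None:
    """Persist a template database to HDF5 (losslessly round-trippable)."""
    if db.n_profiles == 0:
        raise ValueError("refusing to save an empty template database")
    subjects = list(db.subjects)
    with h5py.File(str(path), "w") as f:
        f.attrs["format_version"] = TEMPLATE_DB_FORMAT_VERSION
        f.create_dataset("profiles", data=db.values, compression="gzip")
        f.create_dataset("distances", data=db.distances, compression="gzip")
        f.create_dataset("edge_index", data=db.edge_index)
        f.create_dataset("slice_index", data=db.slice_index)
        f.create_dataset("angle", data=db.angle)
        f.create_dataset("subject_idx", data=db.subject_idx)
        f.create_dataset(
            "subjects", data=np.array(subjects, dtype=h5py.string_dtype())
        )


def load_template_db(path: str | Path):
    """Load a template database saved by :func:`save_template_db`."""
    from .profiles import TemplateDB

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"template database not found: {p}")
    try:
        with h5py.File(str(p), "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != TEMPLATE_DB_FORMAT_VERSION:
                raise FormatError(
                    f"{p}: template DB format version {version} "
                    f"(expected {TEMPLATE_DB_FORMAT_VERSION})"
                )
            db = TemplateDB(
                values=f["profiles"][...],
                distances=f["distances"][...],
                edge_index=f["edge_index"][...],
                slice_index=f["slice_index"][...],
                angle=f["angle"][...],
                subject_idx=f["subject_idx"][...],
                subjects=[s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["subjects"][...]],
            )
    except OSError as exc:  # truncated / non-HDF5 container
        raise FormatError(f"{p}: not a readable template DB ({exc})") from exc
    return db
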