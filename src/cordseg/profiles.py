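"""Radial gradient profiles: the 1-D arrays that drive the matching.

From a center point, rays are cast in 2-degree increments (179 per slice).
Each ray is walked outward in 0.1 mm world steps; every time the nearest voxel
changes, that voxel's gradient value is appended, until exactly 70 voxels have
been collected (~27 mm at 0.39 mm in-plane spacing, direction-dependent since
voxels are anisotropic). Steps beyond the image border contribute zeros, so a
profile always has exactly 70 entries.

Templates are profiles extracted from a manually (here: analytically) masked
volume and additionally carry the edge index: the last voxel of the profile's
walk that lies inside the mask — the cord/CSF boundary as seen along that ray.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .io import Mask, Volume
from .spline import SplineModel

N_PROFILE = 70  #: samples per radial profile
STEP_MM = 0.1  #: walk increment along the ray
ANGLE_STEP_DEG = 2.0
N_ANGLES = 179  #: radial lines per slice (0, 2, ..., 356 degrees)


def slice_angles() -> np.ndarray:
    """The per-slice radial directions, degrees: {0, 2, ..., 356}."""
    return np.arange(N_ANGLES) * ANGLE_STEP_DEG


@dataclass
class RadialProfile:
    """A single 70-sample radial gradient array.

    ``distances`` holds the walked distance (mm) at which each voxel was first
    encountered; ``edge_index`` is present only for templates.
    """

    values: np.ndarray
    distances: np.ndarray
    voxel_path: np.ndarray  # (70, 3) voxel indices, -1 rows beyond the border
    edge_index: int | None = None
    slice_index: int = -1
    angle: float = 0.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (N_PROFILE,):
            raise ValueError(f"profile must have exactly {N_PROFILE} values")


@dataclass
class TemplateDB:
    """All template profiles from one or more ground-truth subjects,
    stored as parallel arrays (rows = radials)."""

    values: np.ndarray  # (n, 70) float32
    distances: np.ndarray  # (n, 70) float32
    edge_index: np.ndarray  # (n,) int16
    slice_index: np.ndarray  # (n,) int32
    angle: np.ndarray  # (n,) float32, degrees
    subject_idx: np.ndarray  # (n,) int32 into subjects
    subjects: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.distances = np.asarray(self.distances, dtype=np.float32)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int16)
        self.slice_index = np.asarray(self.slice_index, dtype=np.int32)
        self.angle = np.asarray(self.angle, dtype=np.float32)
        self.subject_idx = np.asarray(self.subject_idx, dtype=np.int32)
        if self.n_profiles == 0 or not self.subjects:
            raise ValueError("template DB must contain at least one profile")
        if np.any((self.edge_index < 0) | (self.edge_index >= N_PROFILE)):
            raise ValueError("edge indices must lie in [0, 69]")

    @property
    def n_profiles(self) -> int:
        return self.values.shape[0]

    def merge(self, other: "TemplateDB") -> "TemplateDB":
        """Concatenate two databases (multi-subject ground truth)."""
        offset = len(self.subjects)
        return TemplateDB(
            values=np.vstack([self.values, other.values]),
            distances=np.vstack([self.distances, other.distances]),
            edge_index=np.concatenate([self.edge_index, other.edge_index]),
            slice_index=np.concatenate([self.slice_index, other.slice_index]),
            angle=np.concatenate([self.angle, other.angle]),
            subject_idx=np.concatenate(
                [self.subject_idx, other.subject_idx + offset]),
            subjects=self.subjects + other.subjects,
        )


@dataclass
class TestArraySet:
    """Test profiles extracted at evenly spaced stations along the spline."""

    values: np.ndarray  # (n_slices * 179, 70)
    distances: np.ndarray
    slice_index: np.ndarray  # station index per profile
    angle: np.ndarray  # degrees per profile
    station_z: np.ndarray  # (n_slices,) arc lengths mm
    station_centers: np.ndarray  # (n_slices, 3) world mm

    @property
    def n_profiles(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return len(self.station_z)


def _extract_fan(grad: Volume, center: np.ndarray, e1: np.ndarray,
                 e2: np.ndarray, angles_deg: np.ndarray,
                 n: int = N_PROFILE, step: float = STEP_MM):
    """Walk all rays of a fan at once.

    Returns (values, distances, paths, inbounds) with leading axis = angle.
    The walk dedupes consecutive nearest voxels: a new profile entry is made
    only when the nearest voxel changes, which makes 70 entries span roughly
    70 voxel widths along the ray direction.
    """
    center = np.asarray(center, dtype=float)
    inv = np.linalg.inv(grad.affine)
    cvox = center @ inv[:3, :3].T + inv[:3, 3]
    if np.any(cvox < -0.5) or np.any(cvox > np.array(grad.shape) - 0.5):
        raise GeometryError(f"profile center {center} is outside the grid")
    rad = np.deg2rad(angles_deg)
    dirs = np.cos(rad)[:, None] * e1[None, :] + np.sin(rad)[:, None] * e2[None, :]
    # snap numerically-zero components so axis-aligned rays round stably
    dirs[np.abs(dirs) < 1e-12] = 0.0
    n_steps = int(np.ceil(n * float(np.max(grad.spacing)) / step * 1.15)) + 8
    A = len(angles_deg)
    r = np.arange(n_steps) * step
    pts = center[None, None, :] + r[None, :, None] * dirs[:, None, :]
    vox = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(np.int32)
    changed = np.empty((A, n_steps), dtype=bool)
    changed[:, 0] = True
    changed[:, 1:] = np.any(vox[:, 1:] != vox[:, :-1], axis=2)

    values = np.zeros((A, n), dtype=np.float32)
    dists = np.zeros((A, n), dtype=np.float32)
    paths = np.full((A, n, 3), -1, dtype=np.int32)
    shape = np.array(grad.shape)
    data = grad.data
    for a in range(A):
        sel = np.flatnonzero(changed[a])
        if len(sel) < n:  # pathological direction; pad with the last voxel
            sel = np.concatenate([sel, np.full(n - len(sel), sel[-1])])
        sel = sel[:n]
        idx = vox[a, sel]
        inb = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
        vals = np.zeros(n, dtype=np.float32)
        if inb.any():
            ii = idx[inb]
            vals[inb] = data[ii[:, 0], ii[:, 1], ii[:, 2]]
        values[a] = vals
        dists[a] = r[sel]
        paths[a, inb] = idx[inb]
    inbounds = paths[:, :, 0] >= 0
    return values, dists, paths, inbounds


def extract_profile(grad: Volume, center: np.ndarray, direction: np.ndarray,
                    slice_index: int = -1, angle: float = 0.0) -> RadialProfile:
    """Extract one radial profile along a world-space unit ``direction``."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    # a fan of one ray: e1 = direction, angle 0
    e2 = np.zeros(3)
    values, dists, paths, _ = _extract_fan(
        grad, center, direction, e2, np.array([0.0]))
    return RadialProfile(values=values[0], distances=dists[0],
                         voxel_path=paths[0], slice_index=slice_index,
                         angle=angle)


def _edge_from_inside(inside: np.ndarray) -> int | None:
    """Last voxel of the contiguous inside-run from the center, bridging
    single-voxel holes (mask-noise tolerance). None if the center is outside."""
    if not inside[0]:
        return None
    zeros = ~inside
    dbl = zeros[:-1] & zeros[1:]
    stop = int(np.argmax(dbl)) + 1 if dbl.any() else len(inside)
    run = np.flatnonzero(inside[:stop])
    return int(run[-1])


def build_template_db(grad: Volume, manual_mask: Mask,
                      subject_id: str = "subject") -> TemplateDB:
    """Build the template database from a gradient volume and its mask.

    For every axial slice with mask voxels: the slice centroid (unweighted
    mean of mask-voxel world coordinates) is the ray origin; 179 profiles are
    extracted in the axial plane; each profile's edge index is the last voxel
    of its walk inside the mask.
    """
    if not grad.same_grid(manual_mask):
        raise GeometryError("gradient volume and mask are on different grids")
    mdata = manual_mask.data
    angles = slice_angles()
    # axial in-plane frame from the affine's first two columns
    u = grad.affine[:3, 0] / np.linalg.norm(grad.affine[:3, 0])
    v = grad.affine[:3, 1] / np.linalg.norm(grad.affine[:3, 1])
    all_values, all_dists, all_edges = [], [], []
    all_slices, all_angles = [], []
    slice_counts = mdata.sum(axis=(0, 1))
    for k in np.flatnonzero(slice_counts):
        if slice_counts[k] < 2:
            warnings.warn(
                f"slice {k}: degenerate single-voxel cross-section skipped",
                stacklevel=2,
            )
            continue
        ii, jj = np.nonzero(mdata[:, :, k])
        centroid = grad.voxel_to_world(
            np.column_stack([ii, jj, np.full_like(ii, k)]).astype(float)
        ).mean(axis=0)
        values, dists, paths, inb = _extract_fan(grad, centroid, u, v, angles)
        inside = np.zeros(paths.shape[:2], dtype=bool)
        flat = paths[inb]
        inside[inb] = mdata[flat[:, 0], flat[:, 1], flat[:, 2]] > 0
        for a in range(len(angles)):
            edge = _edge_from_inside(inside[a])
            if edge is None:
                edge = 0
            all_values.append(values[a])
            all_dists.append(dists[a])
            all_edges.append(edge)
            all_slices.append(k)
            all_angles.append(angles[a])
    if not all_values:
        raise GeometryError("mask is empty; no templates extracted")
    n = len(all_values)
    return TemplateDB(
        values=np.array(all_values, dtype=np.float32),
        distances=np.array(all_dists, dtype=np.float32),
        edge_index=np.array(all_edges, dtype=np.int16),
        slice_index=np.array(all_slices, dtype=np.int32),
        angle=np.array(all_angles, dtype=np.float32),
        subject_idx=np.zeros(n, dtype=np.int32),
        subjects=[subject_id],
    )


def extract_test_arrays(grad: Volume, spline: SplineModel,
                        n_slices: int = 100) -> TestArraySet:
    """Extract 179 test profiles at each of ``n_slices`` stations evenly
    spaced in arc length from z = 0 to the spline's end (17,900 by default).
    Test profiles lie in the plane orthogonal to the local tangent and carry
    no edge index."""
    angles = slice_angles()
    station_z = np.linspace(0.0, spline.total_length, n_slices)
    ts = spline.t_at_arc_length(station_z) if n_slices > 1 else np.array(
        [spline.t_at_arc_length(0.0)])
    values, dists = [], []
    sl_idx, angs = [], []
    centers = []
    for s, t in enumerate(np.atleast_1d(ts)):
        center = spline.evaluate(float(t))
        e1, e2, _ = spline.frame(float(t))
        try:
            v, d, _, _ = _extract_fan(grad, center, e1, e2, angles)
        except GeometryError as exc:
            raise GeometryError(
                f"spline exits the volume at z={station_z[s]:.2f} mm"
            ) from exc
        values.append(v)
        dists.append(d)
        sl_idx.append(np.full(len(angles), s, dtype=np.int32))
        angs.append(angles)
        centers.append(center)
    return TestArraySet(
        values=np.vstack(values).astype(np.float32),
        distances=np.vstack(dists).astype(np.float32),
        slice_index=np.concatenate(sl_idx),
        angle=np.concatenate(angs).astype(np.float32),
        station_z=station_z,
        station_centers=np.array(centers),
    )
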