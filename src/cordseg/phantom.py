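"""Synthetic spinal cord phantoms with analytic ground truth.

Each phantom emulates the appearance of a T2-weighted cervical cord volume:
a darker tubular cord with a varying radius (the cervical enlargement rises
toward C5-C6 and falls again), surrounded by a bright CSF ring, embedded in
mid-intensity tissue. Degradations reproduce the failure modes real images
show: additive noise, z-ranges where the CSF ring is obliterated (replaced by
tissue intensity), and thin dark rootlet-like streaks crossing the ring.

The ground truth is analytic: the centerline is a closed-form curve, and the
truth mask is exactly the set of voxels whose center lies within the local
radius of the centerline (nearest-point distance), so downstream metric
oracles are exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .io import Mask, Volume, write_mask, write_volume

ROOTLET_LABELS = ("C3", "C4", "C5", "C6", "C7", "C8")


@dataclass
class CenterlineParams:
    """Sinusoidal in-plane deflection of the cord axis vs. z.

    By default the deflection is confined to one sagittal-like plane (x only);
    ``helical=True`` adds the quadrature component in y.
    """

    amplitude_mm: float = 2.0
    wavelength_mm: float = 120.0
    phase: float = 0.0
    helical: bool = False


@dataclass
class Intensities:
    """Mean tissue-class intensities (arbitrary units, T2-like ordering
    CSF > tissue > cord by default)."""

    cord: float = 60.0
    csf: float = 240.0
    tissue: float = 120.0


@dataclass
class RootletArtifacts:
    """Thin dark streaks crossing the CSF ring at the rootlet levels."""

    count: int = 12  # up to 2 per C3..C8 level (left/right)
    radius_mm: float = 0.35
    intensity: float = 10.0


@dataclass
class PhantomConfig:
    # odd in-plane counts center the cord on a voxel center, which keeps
    # axis-aligned ray walks away from rounding knife-edges
    grid_shape: tuple[int, int, int] = (63, 63, 200)
    voxel_spacing: tuple[float, float, float] = (0.3906, 0.3906, 0.3)
    centerline_params: CenterlineParams = field(default_factory=CenterlineParams)
    #: cord radius mm as piecewise-linear (z_mm, r_mm) knots
    radius_profile: tuple[tuple[float, float], ...] = (
        (0.0, 3.8), (30.0, 4.6), (60.0, 3.9)
    )
    csf_thickness_mm: float = 1.5
    intensities: Intensities = field(default_factory=Intensities)
    noise_sd: float = 5.0
    obliteration_intervals: tuple[tuple[float, float], ...] = ()
    rootlet_artifacts: RootletArtifacts = field(default_factory=RootletArtifacts)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.voxel_spacing):
            raise GeometryError("voxel spacing must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.csf_thickness_mm < 0:
            raise GeometryError("csf_thickness must be nonnegative")

    @property
    def length_mm(self) -> float:
        return (self.grid_shape[2] - 1) * self.voxel_spacing[2]

    def radius_at(self, z) -> np.ndarray:
        knots = np.asarray(self.radius_profile, dtype=float)
        return np.interp(z, knots[:, 0], knots[:, 1])

    def center_at(self, z) -> np.ndarray:
        """Analytic centerline point(s) at world z (mm)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        nx, ny, _ = self.grid_shape
        sx, sy, _ = self.voxel_spacing
        cx0 = (nx - 1) / 2 * sx
        cy0 = (ny - 1) / 2 * sy
        cp = self.centerline_params
        arg = 2 * np.pi * z / cp.wavelength_mm + cp.phase
        x = cx0 + cp.amplitude_mm * np.sin(arg)
        y = np.full_like(z, cy0)
        if cp.helical:
            y = cy0 + cp.amplitude_mm * np.cos(arg)
        return np.stack([x, y, z], axis=-1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "centerline_params" in d and isinstance(d["centerline_params"], dict):
            d["centerline_params"] = CenterlineParams(**d["centerline_params"])
        if "intensities" in d and isinstance(d["intensities"], dict):
            d["intensities"] = Intensities(**d["intensities"])
        if "rootlet_artifacts" in d and isinstance(d["rootlet_artifacts"], dict):
            d["rootlet_artifacts"] = RootletArtifacts(**d["rootlet_artifacts"])
        for key in ("grid_shape", "voxel_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        if "radius_profile" in d:
            d["radius_profile"] = tuple(tuple(k) for k in d["radius_profile"])
        if "obliteration_intervals" in d:
            d["obliteration_intervals"] = tuple(
                tuple(k) for k in d["obliteration_intervals"]
            )
        return cls(**d)


@dataclass
class PhantomCase:
    """A generated phantom: image volume plus analytic ground truth."""

    volume: Volume
    truth_mask: Mask
    truth_centerline: np.ndarray  # (nz, 3) world mm, one point per axial slice
    rootlet_markers: dict  # label -> {"rostral": (3,), "caudal": (3,)}
    config: PhantomConfig
    # nearest-centerline geometry cached for degradations
    _rhat: np.ndarray | None = None
    _zcurve: np.ndarray | None = None


def _curve_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel distance to the analytic centerline and the arc position
    (world z of the nearest curve sample), via a dense nearest-point search."""
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.voxel_spacing
    z_dense = np.arange(0.0, config.length_mm + 1e-9, 0.05)
    samples = config.center_at(z_dense)
    tree = cKDTree(samples)
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack(
        [ix.ravel() * sx, iy.ravel() * sy, iz.ravel() * sz], axis=1
    )
    dist, k = tree.query(pts, workers=-1)
    rhat = dist.reshape(nx, ny, nz).astype(np.float32)
    zcurve = z_dense[k].reshape(nx, ny, nz).astype(np.float32)
    return rhat, zcurve


def _check_geometry(config: PhantomConfig) -> None:
    z = np.linspace(0, config.length_mm, 256)
    centers = config.center_at(z)
    reach = config.radius_at(z) + config.csf_thickness_mm
    nx, ny, _ = config.grid_shape
    sx, sy, _ = config.voxel_spacing
    if (np.any(centers[:, 0] - reach < 0)
            or np.any(centers[:, 0] + reach > (nx - 1) * sx)
            or np.any(centers[:, 1] - reach < 0)
            or np.any(centers[:, 1] + reach > (ny - 1) * sy)):
        raise GeometryError(
            "cord plus CSF ring does not fit inside the grid everywhere"
        )


def _rootlet_placements(config: PhantomConfig) -> list[tuple[float, int]]:
    """(z_mm, side) placements of rootlet streaks: one left/right pair at the
    middle of each C3..C8 segment."""
    bounds = _segment_bounds(config)
    mids = (bounds[:-1] + bounds[1:]) / 2
    placements = []
    for z in mids:
        placements.append((float(z), +1))
        placements.append((float(z), -1))
    return placements


def _segment_bounds(config: PhantomConfig) -> np.ndarray:
    """Seven z positions bounding the six contiguous C3..C8 segments."""
    L = config.length_mm
    return np.linspace(0.12 * L, 0.88 * L, len(ROOTLET_LABELS) + 1)


def _render_rootlets(data: np.ndarray, config: PhantomConfig,
                     rhat: np.ndarray, zcurve: np.ndarray,
                     artifacts: RootletArtifacts) -> None:
    """Dark thin cylinders crossing the CSF ring, oriented radially (+/- y)."""
    if artifacts.count <= 0:
        return
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.voxel_spacing
    placements = _rootlet_placements(config)[: artifacts.count]
    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    zs = np.arange(nz) * sz
    for z_a, side in placements:
        center = config.center_at(z_a)[0]
        r_cord = float(config.radius_at(z_a))
        k_sel = np.flatnonzero(np.abs(zs - z_a) <= artifacts.radius_mm)
        i_sel = np.flatnonzero(np.abs(xs - center[0]) <= artifacts.radius_mm)
        if side > 0:
            j_sel = np.flatnonzero(
                (ys >= center[1] + r_cord - 0.2)
                & (ys <= center[1] + r_cord + config.csf_thickness_mm + 0.3)
            )
        else:
            j_sel = np.flatnonzero(
                (ys <= center[1] - r_cord + 0.2)
                & (ys >= center[1] - r_cord - config.csf_thickness_mm - 0.3)
            )
        ii, jj, kk = np.ix_(i_sel, j_sel, k_sel)
        # only darken the ring, never the cord interior
        ring = rhat[ii, jj, kk] > config.radius_at(zcurve[ii, jj, kk])
        sub = data[ii, jj, kk]
        sub[ring] = artifacts.intensity
        data[ii, jj, kk] = sub


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a phantom volume, truth mask, analytic centerline, and
    rootlet markers. Deterministic given the config (including its seed)."""
    _check_geometry(config)
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.voxel_spacing
    rhat, zcurve = _curve_geometry(config)
    radius = config.radius_at(zcurve)
    cord = rhat <= radius
    ring = (rhat > radius) & (rhat <= radius + config.csf_thickness_mm)

    inten = config.intensities
    data = np.full(config.grid_shape, inten.tissue, dtype=np.float32)
    data[ring] = inten.csf
    data[cord] = inten.cord

    affine = np.diag([sx, sy, sz, 1.0])
    spacing = np.array([sx, sy, sz])
    volume = Volume(data=data, spacing=spacing, affine=affine)
    truth_mask = Mask(data=cord.astype(np.uint8), spacing=spacing.copy(),
                      affine=affine.copy())
    zk = np.arange(nz) * sz
    centerline = config.center_at(zk)

    bounds = _segment_bounds(config)
    markers = {}
    for i, label in enumerate(ROOTLET_LABELS):
        zr, zc = bounds[i], bounds[i + 1]
        # marker points sit at the cord surface (small radial offset)
        pr = config.center_at(zr)[0] + np.array(
            [config.radius_at(zr), 0.0, 0.0])
        pc = config.center_at(zc)[0] + np.array(
            [config.radius_at(zc), 0.0, 0.0])
        markers[label] = {"rostral": pr, "caudal": pc}

    case = PhantomCase(volume=volume, truth_mask=truth_mask,
                       truth_centerline=centerline, rootlet_markers=markers,
                       config=config, _rhat=rhat, _zcurve=zcurve)
    return degrade(case, noise_sd=config.noise_sd,
                   obliteration_intervals=config.obliteration_intervals,
                   rootlet_artifacts=config.rootlet_artifacts,
                   seed=config.seed)


def degrade(case: PhantomCase, noise_sd: float = 0.0,
            obliteration_intervals=(), rootlet_artifacts=None,
            seed: int | None = None) -> PhantomCase:
    """Apply intensity degradations; the truth mask and centerline are
    untouched by construction (only the image intensities change)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    config = case.config
    rhat, zcurve = case._rhat, case._zcurve
    if rhat is None or zcurve is None:
        rhat, zcurve = _curve_geometry(config)
    data = case.volume.data.astype(np.float32).copy()
    radius = config.radius_at(zcurve)
    ring = (rhat > radius) & (rhat <= radius + config.csf_thickness_mm)

    zw = np.arange(config.grid_shape[2]) * config.voxel_spacing[2]
    for z0, z1 in obliteration_intervals:
        in_z = np.zeros_like(ring)
        in_z[:, :, (zw >= z0) & (zw <= z1)] = True
        data[ring & in_z] = config.intensities.tissue

    if rootlet_artifacts is not None:
        _render_rootlets(data, config, rhat, zcurve, rootlet_artifacts)

    if noise_sd > 0:
        rng = np.random.default_rng(
            config.seed if seed is None else seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(
            np.float32)

    volume = Volume(data=data, spacing=case.volume.spacing.copy(),
                    affine=case.volume.affine.copy())
    return PhantomCase(volume=volume, truth_mask=case.truth_mask,
                       truth_centerline=case.truth_centerline,
                       rootlet_markers=case.rootlet_markers, config=config,
                       _rhat=rhat, _zcurve=zcurve)


def write_phantom(case: PhantomCase, out_dir: str | Path,
                  stem: str = "phantom") -> dict[str, Path]:
    """Write volume + mask as NIfTI and a JSON sidecar (centerline samples,
    rootlet markers, config echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / f"{stem}.nii.gz",
        "mask": out / f"{stem}_mask.nii.gz",
        "sidecar": out / f"{stem}.json",
    }
    write_volume(case.volume, paths["volume"])
    write_mask(case.truth_mask, paths["mask"])
    sidecar = {
        "centerline_mm": case.truth_centerline.tolist(),
        "rootlet_markers_mm": {
            lab: {k: np.asarray(v).tolist() for k, v in mk.items()}
            for lab, mk in case.rootlet_markers.items()
        },
        "config": case.config.to_dict(),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths
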