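"""Validation metrics: Dice, mean centerline distance, Hausdorff distance,
and regional cross-sectional area (CSA).

Dice(A,B) = 2|A∩B| / (|A|+|B|) measures volumetric overlap. MD averages the
per-axial-slice Euclidean distance between two centerlines. HD is the
symmetric maximum of directed maximum point-to-surface distances between the
two segmentation boundaries. CSA divides a region's segmented volume (mm^3)
by the region's centerline arc length (mm); regions are demarcated by nerve
rootlet markers (C3..C8) projected onto a shared centerline spline, so that
centerline disagreement does not contaminate area comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError
from .io import Mask
from .spline import SplineModel


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap coefficient in [0, 1]."""
    if not a.same_grid(b):
        raise GeometryError("masks are on different grids")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def mean_centerline_distance(spline_a: SplineModel, spline_b: SplineModel,
                             slice_zs: np.ndarray) -> float:
    """Average in-plane distance (mm) between two centerlines over the axial
    slices at world z-coordinates ``slice_zs``; the sum is divided by (n-1)
    per the printed convention."""
    ds = []
    for zw in np.asarray(slice_zs, dtype=float):
        pa = spline_a.point_at_world_z(zw)
        pb = spline_b.point_at_world_z(zw)
        if pa is None or pb is None:
            continue
        ds.append(float(np.hypot(pa[0] - pb[0], pa[1] - pb[1])))
    n = len(ds)
    if n < 2:
        raise GeometryError("centerlines share fewer than 2 axial slices")
    return float(np.sum(ds) / (n - 1))


def _boundary_points(mask: Mask) -> np.ndarray:
    """World coordinates of the segmentation surface (boundary voxel
    centers)."""
    data = mask.data > 0
    inner = ndimage.binary_erosion(data)
    ii, jj, kk = np.nonzero(data & ~inner)
    return mask.voxel_to_world(np.column_stack([ii, jj, kk]).astype(float))


def hausdorff(a: Mask, b: Mask) -> float:
    """Symmetric Hausdorff distance (mm) between segmentation surfaces."""
    if not a.same_grid(b):
        raise GeometryError("masks are on different grids")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise ValueError("Hausdorff is undefined for an empty mask")
    pa = _boundary_points(a)
    pb = _boundary_points(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class RegionSpec:
    """A rostral/caudal-bounded cord segment on a given spline."""

    label: str
    z_start: float  # arc length mm, rostral
    z_end: float  # arc length mm, caudal

    def __post_init__(self) -> None:
        if not self.z_start < self.z_end:
            raise GeometryError(
                f"region {self.label}: rostral z must precede caudal z"
            )

    @property
    def length(self) -> float:
        return self.z_end - self.z_start


def region_from_markers(spline: SplineModel, rostral: np.ndarray,
                        caudal: np.ndarray, label: str = "") -> RegionSpec:
    """Project the two markers onto the spline; the arc-length interval
    between them defines the region (radial offsets of the markers do not
    matter)."""
    z0 = spline.euclid_to_cyl(np.asarray(rostral, dtype=float)).z
    z1 = spline.euclid_to_cyl(np.asarray(caudal, dtype=float)).z
    if z0 >= z1:
        raise GeometryError(
            f"rostral marker projects caudal of the caudal marker "
            f"({z0:.2f} >= {z1:.2f} mm)"
        )
    return RegionSpec(label=label, z_start=z0, z_end=z1)


def regional_csa(mask: Mask, spline: SplineModel, region: RegionSpec) -> float:
    """Cross-sectional area (mm^2) of the mask over the region: segmented
    volume divided by the region's centerline arc length. Voxels are assigned
    to the region by the arc length of their nearest point on the shared
    spline."""
    if region.length <= 0:
        raise GeometryError("zero-length region")
    ii, jj, kk = np.nonzero(mask.data)
    if len(ii) == 0:
        return 0.0
    pts = mask.voxel_to_world(np.column_stack([ii, jj, kk]).astype(float))
    z = spline.project_arc_lengths(pts)
    count = int(np.sum((z >= region.z_start) & (z < region.z_end)))
    return count * mask.voxel_volume / region.length


def csa_abs_diff(csa1: float, csa2: float) -> float:
    """Absolute difference in cross-sectional area."""
    return abs(csa2 - csa1)


def cohort_report(pair_metrics: list[dict],
                  regional: list[dict] | None = None) -> dict:
    """Aggregate per-pair metrics into a cohort report.

    ``pair_metrics``: one dict per compared pair with keys ``dice``, ``md``,
    ``hd`` (each pair's MD/HD already averaged within that subject).
    ``regional``: optional dicts with ``label``, ``csa_a``, ``csa_b``.

    Returns mean +/- sample sd (n-1) and min/max per metric, plus per-region
    mean CSA and mean absolute CSA difference.
    """
    if not pair_metrics:
        raise ValueError("no pairs to aggregate")
    df = pd.DataFrame(pair_metrics)
    summary = {}
    for col in ("dice", "md", "hd"):
        if col in df:
            vals = df[col].to_numpy(dtype=float)
            summary[col] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(len(vals)),
            }
    report = {"pairs": summary}
    if regional:
        rdf = pd.DataFrame(regional)
        if rdf["label"].isna().any():
            raise ValueError("regional entries must carry region labels")
        rows = {}
        for label, grp in rdf.groupby("label", sort=False):
            diffs = (grp["csa_a"] - grp["csa_b"]).abs()
            rows[label] = {
                "mean_csa_a": float(grp["csa_a"].mean()),
                "mean_csa_b": float(grp["csa_b"].mean()),
                "mean_abs_diff": float(diffs.mean()),
                "n": int(len(grp)),
            }
        report["regions"] = rows
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a cohort report to a tidy DataFrame (for CSV export)."""
    rows = []
    for metric, stats in report.get("pairs", {}).items():
        rows.append({"kind": "pair", "name": metric, **stats})
    for label, stats in report.get("regions", {}).items():
        rows.append({"kind": "region", "name": label, **stats})
    return pd.DataFrame(rows)
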