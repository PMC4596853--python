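"""The segmentation engine: 1-D normalized template matching.

Every test profile is compared against every template in the database by
normalized cross-correlation (population-normalized, so NCC is invariant to
positive affine intensity changes). The matcher aims to find 50 templates at
the highest threshold, starting at 1.00 and dropping by 200 basis points
(0.02) until 50 qualify; the cord edge along that ray is then the average of
the matched templates' edge indices. Below a floor of 0.30 the top 50 by raw
NCC are used and the cell is flagged as a fallback.

Sparse per-station edges are median-smoothed (optionally, in a cascade over
the angular then longitudinal axes), linearly interpolated to every axial
slice, rasterized into a star-convex region about the slice center, and the
resulting mask's per-slice centroids re-fit a refined 500-control-point
centerline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .io import Mask, Volume, gradient_magnitude
from .profiles import (N_ANGLES, N_PROFILE, STEP_MM, RadialProfile,
                       TemplateDB, TestArraySet, extract_test_arrays,
                       slice_angles)
from .spline import SplineModel, fit_spline

#: numerical slack when snapping an NCC value onto the threshold schedule
NCC_EPS = 1e-6

# EdgeField provenance flags
FLAG_MATCHED = 1
FLAG_INTERPOLATED = 2
FLAG_SMOOTHED = 4
FLAG_FALLBACK = 8


def ncc(f: np.ndarray, t: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-length arrays.

    Population (1/n) normalization; a constant array has zero variance and
    the similarity is defined as 0 (such profiles are excluded from matching).
    """
    f = np.asarray(f, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if f.shape != t.shape or f.ndim != 1:
        raise ValueError("ncc needs two equal-length 1-D arrays")
    n = f.size
    fc = f - f.mean()
    tc = t - t.mean()
    sf = np.sqrt((fc ** 2).mean())
    st = np.sqrt((tc ** 2).mean())
    if sf == 0 or st == 0:
        return 0.0
    return float((fc * tc).mean() / (sf * st))


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that a dot product equals NCC; constant rows -> zero
    vectors (their NCC with anything is 0) and a flag."""
    X = np.asarray(X, dtype=np.float32)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    sd = np.sqrt((Xc ** 2).mean(axis=1, keepdims=True))
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return Xc / (sd * np.sqrt(X.shape[1])), constant


def _snap_threshold(c: float, step: float) -> float:
    """Largest schedule value (1.00, 1.00-step, ...) not exceeding c."""
    return min(1.0, np.floor((c + NCC_EPS) / step) * step)


@dataclass
class MatchResult:
    """Outcome of matching one test profile against the database."""

    template_indices: np.ndarray
    ncc_values: np.ndarray
    final_threshold: float
    fallback: bool
    inferred_edge: float


@dataclass
class MatchBatch:
    """Vectorized matching outcome for a whole set of test profiles."""

    inferred_edge: np.ndarray  # (K,) fractional indices
    final_threshold: np.ndarray  # (K,)
    fallback: np.ndarray  # (K,) bool
    matched_idx: np.ndarray  # (K, k) template row indices
    ncc_values: np.ndarray  # (K, k)


def match_batch(test_values: np.ndarray, db: TemplateDB, n_target: int = 50,
                step: float = 0.02, floor: float = 0.30,
                chunk: int = 1024) -> MatchBatch:
    """Match every test profile against every template.

    The threshold schedule is 1.00, 0.98, ...; the final threshold for a
    profile is the first (highest) level at which at least ``n_target``
    templates qualify — equivalently the schedule value at or below the
    n_target-th largest NCC. Ties are broken by database insertion order.
    """
    tests = np.atleast_2d(np.asarray(test_values, dtype=np.float32))
    K = tests.shape[0]
    M = db.n_profiles
    k = n_target
    if M < n_target:
        warnings.warn(
            f"database has only {M} templates (< {n_target}); using all",
            stacklevel=2,
        )
        k = M
    Dn, d_const = _normalize_rows(db.values)
    Tn, _ = _normalize_rows(tests)
    edges = db.edge_index.astype(np.float64)

    inferred = np.empty(K)
    final_thr = np.empty(K)
    fallback = np.zeros(K, dtype=bool)
    matched = np.empty((K, k), dtype=np.int64)
    nccs = np.empty((K, k), dtype=np.float32)

    for start in range(0, K, chunk):
        sl = slice(start, min(start + chunk, K))
        C = Tn[sl] @ Dn.T  # (c, M) NCC values
        if k == M:
            order = np.argsort(-C, axis=1, kind="stable")
            top = order[:, :k]
        else:
            part = np.argpartition(-C, k - 1, axis=1)[:, :k]
            part.sort(axis=1)  # ascending index -> stable tie-break below
            vals = np.take_along_axis(C, part, axis=1)
            top = np.take_along_axis(
                part, np.argsort(-vals, axis=1, kind="stable"), axis=1)
            # rows where schedule ties straddle the partition boundary
            kth = np.take_along_axis(C, top[:, -1:], axis=1)[:, 0]
            tied = (C >= kth[:, None] - 0).sum(axis=1) > k
            for r in np.flatnonzero(tied):
                cand = np.flatnonzero(C[r] >= kth[r])
                cand = cand[np.argsort(-C[r, cand], kind="stable")]
                top[r] = cand[:k]
        rows = np.arange(top.shape[0])[:, None]
        vals = C[rows, top]
        matched[sl] = top
        nccs[sl] = vals
        c_k = vals[:, -1].astype(np.float64)
        thr = np.minimum(1.0, np.floor((c_k + NCC_EPS) / step) * step)
        fb = thr < floor - NCC_EPS
        thr[fb] = floor
        final_thr[sl] = thr
        fallback[sl] = fb
        inferred[sl] = edges[top].mean(axis=1)
    return MatchBatch(inferred_edge=inferred, final_threshold=final_thr,
                      fallback=fallback, matched_idx=matched, ncc_values=nccs)


def find_matches(test: RadialProfile | np.ndarray, db: TemplateDB,
                 n_target: int = 50, step: float = 0.02,
                 floor: float = 0.30) -> MatchResult:
    """Match a single test profile (see :func:`match_batch`)."""
    values = test.values if isinstance(test, RadialProfile) else test
    batch = match_batch(values[None, :], db, n_target=n_target, step=step,
                        floor=floor)
    return MatchResult(
        template_indices=batch.matched_idx[0],
        ncc_values=batch.ncc_values[0],
        final_threshold=float(batch.final_threshold[0]),
        fallback=bool(batch.fallback[0]),
        inferred_edge=float(batch.inferred_edge[0]),
    )


def infer_edge(match: MatchResult) -> float:
    """Edge as the arithmetic mean of the matched templates' edge indices."""
    return float(match.inferred_edge)


def edge_index_to_mm(edge: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Convert fractional edge indices to mm along their own rays.

    The boundary corresponding to integer edge e lies between voxel e and
    voxel e+1 of the walk; the walk first sees voxel e+1 at distances[e+1],
    half a step after crossing into it, so the boundary estimate is
    distances[e+1] - step/2 (linearly interpolated for fractional e).
    """
    edge = np.atleast_1d(np.asarray(edge, dtype=np.float64))
    distances = np.atleast_2d(distances)
    xq = edge + 1.0
    j = np.clip(np.floor(xq).astype(int), 0, N_PROFILE - 2)
    frac = xq - j
    rows = np.arange(distances.shape[0])
    d0 = distances[rows, j]
    d1 = distances[rows, j + 1]
    return d0 + frac * (d1 - d0) - STEP_MM / 2


@dataclass
class EdgeField:
    """Per-(slice, angle) edge distances: the intermediate segmentation.

    ``axial_pos`` holds each row's (possibly fractional) axial-slice
    coordinate; ``centers`` the ray origin per row; ``mm``/``index`` the edge
    in world mm along the ray and in radial-index units; ``flags`` provenance
    bits (matched / interpolated / smoothed / fallback).
    """

    mm: np.ndarray  # (n, 179)
    index: np.ndarray  # (n, 179)
    flags: np.ndarray  # (n, 179) uint8
    axial_pos: np.ndarray  # (n,)
    centers: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if np.any(self.mm < 0) or np.any(self.index < 0) \
                or np.any(self.index > N_PROFILE - 1):
            raise ValueError("edge distances out of range")

    @property
    def n_slices(self) -> int:
        return self.mm.shape[0]


def interpolate_edge_field(sparse: EdgeField, n_axial: int,
                           spline: SplineModel, volume: Volume) -> EdgeField:
    """Linearly interpolate the sparse per-station edges, per angle, onto
    every integer axial slice between the first and last station (no
    extrapolation beyond them)."""
    if sparse.n_slices < 2:
        raise GeometryError("need at least 2 matched slices to interpolate")
    pos = sparse.axial_pos
    order = np.argsort(pos)
    pos = pos[order]
    j0 = int(np.ceil(pos[0] - 1e-9))
    j1 = int(np.floor(pos[-1] + 1e-9))
    j0 = max(j0, 0)
    j1 = min(j1, n_axial - 1)
    if j1 < j0:
        raise GeometryError("stations bracket no axial slice")
    js = np.arange(j0, j1 + 1)
    mm = np.empty((len(js), N_ANGLES))
    idx = np.empty((len(js), N_ANGLES))
    for a in range(N_ANGLES):
        mm[:, a] = np.interp(js, pos, sparse.mm[order, a])
        idx[:, a] = np.interp(js, pos, sparse.index[order, a])
    flags = np.full((len(js), N_ANGLES), FLAG_INTERPOLATED, dtype=np.uint8)
    # rows essentially coinciding with a station keep their matched flags
    near = np.abs(js[:, None] - pos[None, :]) < 0.5
    for r, row in enumerate(near):
        if row.any():
            s = order[int(np.argmax(row))]
            flags[r] = sparse.flags[s]
    sz = volume.spacing[2]
    centers = np.empty((len(js), 3))
    for r, j in enumerate(js):
        zw = volume.voxel_to_world(np.array([0.0, 0.0, float(j)]))[2]
        p = spline.point_at_world_z(zw)
        if p is None:  # spline doesn't reach this plane; reuse nearest station
            s = order[int(np.argmin(np.abs(pos - j)))]
            p = sparse.centers[s]
        centers[r] = p
    return EdgeField(mm=mm, index=np.clip(idx, 0, N_PROFILE - 1), flags=flags,
                     axial_pos=js.astype(float), centers=centers)


def smooth_edge_field(fieldd: EdgeField,
                      kernels: tuple[int, ...] = (5, 7, 9)) -> EdgeField:
    """Cascade of 1-D median filters over the edge distances: for each kernel
    size, first in the axial plane (over the angle axis, circular wrap), then
    along the cord (the slice axis, reflect padding)."""
    for ksz in kernels:
        if ksz % 2 == 0 or ksz < 1:
            raise ValueError(f"median kernel size must be odd, got {ksz}")
    mm = fieldd.mm.copy()
    idx = fieldd.index.copy()
    for ksz in kernels:
        for arr in (mm, idx):
            arr[:] = ndimage.median_filter(arr, size=(1, ksz), mode="wrap")
            arr[:] = ndimage.median_filter(arr, size=(ksz, 1), mode="reflect")
    return EdgeField(mm=mm, index=np.clip(idx, 0, N_PROFILE - 1),
                     flags=fieldd.flags | FLAG_SMOOTHED,
                     axial_pos=fieldd.axial_pos, centers=fieldd.centers)


def rasterize_slice(center: np.ndarray, angles_deg: np.ndarray,
                    edge_mm: np.ndarray, volume: Volume,
                    slice_k: int) -> np.ndarray:
    """Fill one axial slice: a voxel center is inside iff its in-plane polar
    radius about ``center`` is at most the edge distance linearly interpolated
    (with circular wrap) between the two adjacent angles. The result is
    star-convex about the center by construction."""
    nx, ny, _ = volume.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    world = volume.voxel_to_world(
        np.stack([ii.ravel(), jj.ravel(),
                  np.full(ii.size, slice_k)], axis=1).astype(float))
    dx = world[:, 0] - center[0]
    dy = world[:, 1] - center[1]
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    xp = np.concatenate([angles_deg, [360.0]])
    fp = np.concatenate([edge_mm, [edge_mm[0]]])
    lim = np.interp(ang, xp, fp)
    # a zero edge limit marks "no cord along this ray": nothing is filled
    return ((r <= lim) & (lim > 0)).reshape(nx, ny)


def recenter(mask: Mask, n_control: int = 500) -> SplineModel:
    """Refined centerline: per-slice centroids of the segmented mask become
    control points, resampled to exactly ``n_control`` points evenly spaced
    along z. Fragmented slices contribute their largest component's centroid."""
    counts = mask.data.sum(axis=(0, 1))
    ks = np.flatnonzero(counts)
    if len(ks) < 4:
        raise GeometryError("mask must be nonempty on at least 4 slices")
    cents = np.empty((len(ks), 3))
    for n, k in enumerate(ks):
        sl = mask.data[:, :, k]
        lab, nlab = ndimage.label(sl)
        if nlab > 1:
            warnings.warn(f"slice {k}: fragmented segmentation; "
                          "using largest component", stacklevel=2)
            sizes = ndimage.sum_labels(sl > 0, lab, np.arange(1, nlab + 1))
            sl = lab == (1 + int(np.argmax(sizes)))
        ii, jj = np.nonzero(sl)
        cents[n] = mask.voxel_to_world(
            np.column_stack([ii, jj, np.full_like(ii, k)]).astype(float)
        ).mean(axis=0)
    z = cents[:, 2]
    znew = np.linspace(z[0], z[-1], n_control)
    ctrl = np.column_stack([
        np.interp(znew, z, cents[:, 0]),
        np.interp(znew, z, cents[:, 1]),
        znew,
    ])
    return SplineModel(control_points=ctrl)


@dataclass
class SegmentOptions:
    """Tunable parameters of the segmentation pipeline (defaults are the
    method's standard operating point)."""

    n_control: int = 20
    n_slices: int = 100
    n_matches: int = 50
    step: float = 0.02
    floor: float = 0.30
    smooth: bool = False
    kernels: tuple[int, ...] = (5, 7, 9)
    refined_control_points: int = 500
    d0: tuple[float, float, float] | None = None
    gradient_in_plane: bool = False


@dataclass
class SegmentationResult:
    mask: Mask
    refined_spline: SplineModel
    edge_field: EdgeField  # final (interpolated, possibly smoothed) field
    station_field: EdgeField  # sparse per-station matched field
    initial_spline: SplineModel
    meta: dict


def segment(volume: Volume, markings: np.ndarray, db: TemplateDB,
            options: SegmentOptions | None = None) -> SegmentationResult:
    """Run the full pipeline: centerline spline from the markings, gradient
    image, test-array extraction, template matching with the threshold
    schedule, optional median-smoothing cascade, linear interpolation to all
    axial slices, rasterization, and re-centering. Deterministic given its
    inputs."""
    opt = options or SegmentOptions()
    d0 = None if opt.d0 is None else np.asarray(opt.d0, dtype=float)
    spline = fit_spline(markings, n_control=opt.n_control, d0=d0)
    grad = gradient_magnitude(volume, in_plane=opt.gradient_in_plane)
    tests = extract_test_arrays(grad, spline, n_slices=opt.n_slices)
    batch = match_batch(tests.values, db, n_target=opt.n_matches,
                        step=opt.step, floor=opt.floor)
    edge_mm = edge_index_to_mm(batch.inferred_edge, tests.distances)

    n_st = tests.n_slices
    mm = edge_mm.reshape(n_st, N_ANGLES)
    idx = batch.inferred_edge.reshape(n_st, N_ANGLES)
    flags = np.full((n_st, N_ANGLES), FLAG_MATCHED, dtype=np.uint8)
    flags[batch.fallback.reshape(n_st, N_ANGLES)] |= FLAG_FALLBACK
    station_pos = volume.world_to_voxel(tests.station_centers)[:, 2]
    station_field = EdgeField(mm=np.maximum(mm, 0.0), index=idx, flags=flags,
                              axial_pos=station_pos,
                              centers=tests.station_centers)

    working = station_field
    if opt.smooth:
        working = smooth_edge_field(working, kernels=opt.kernels)
    full = interpolate_edge_field(working, volume.shape[2], spline, volume)

    seg = np.zeros(volume.shape, dtype=np.uint8)
    angles = slice_angles()
    for r in range(full.n_slices):
        k = int(round(full.axial_pos[r]))
        seg[:, :, k] = rasterize_slice(full.centers[r], angles, full.mm[r],
                                       volume, k)
    mask = Mask(data=seg, spacing=volume.spacing.copy(),
                affine=volume.affine.copy())
    refined = recenter(mask, n_control=opt.refined_control_points)
    meta = {
        "n_test_arrays": int(tests.n_profiles),
        "n_templates": int(db.n_profiles),
        "n_fallback": int(batch.fallback.sum()),
        "mean_final_threshold": float(batch.final_threshold.mean()),
        "options": {
            "n_control": opt.n_control, "n_slices": opt.n_slices,
            "n_matches": opt.n_matches, "step": opt.step,
            "floor": opt.floor, "smooth": opt.smooth,
            "kernels": list(opt.kernels),
            "refined_control_points": opt.refined_control_points,
        },
    }
    return SegmentationResult(mask=mask, refined_spline=refined,
                              edge_field=full, station_field=station_field,
                              initial_spline=spline, meta=meta)
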