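"""Catmull-Rom centerline spline and generalized cylindrical coordinates.

The cord's central axis is a piecewise-cubic Hermite (Catmull-Rom) curve
through N control points P_1..P_N, with ghost points P_0, P_{N+1} chosen so the
end tangents point at the adjacent control point. The curve parameter t runs
over [0, 1): segment index i = floor(t*(N-1)), local parameter
t' = t*(N-1) - i in [0, 1).

Arc length s(t) = integral of ||p'(t)|| gives the longitudinal coordinate z
(mm from the first control point, the ponto-medullary junction). Together with
an angle theta measured from a fixed reference direction d0 in the plane
orthogonal to the local tangent, and the radial distance r, this forms the
generalized cylindrical system (z, theta, r) in which all radial profiles are
extracted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError

#: maximum radius (mm) for which the nearest-point problem is trusted;
#: beyond this the fixed-frame cylindrical system is ill-conditioned
CAPTURE_RADIUS_MM = 30.0


class CylCoord(NamedTuple):
    """Cylindrical coordinates: arc length z (mm), angle theta (rad, [0, 2pi)),
    radius r (mm)."""

    z: float
    theta: float
    r: float


def _hermite(u: np.ndarray) -> tuple[np.ndarray, ...]:
    u2 = u * u
    u3 = u2 * u
    h00 = 2 * u3 - 3 * u2 + 1
    h10 = u3 - 2 * u2 + u
    h01 = -2 * u3 + 3 * u2
    h11 = u3 - u2
    return h00, h10, h01, h11


def _hermite_d(u: np.ndarray) -> tuple[np.ndarray, ...]:
    u2 = u * u
    d00 = 6 * u2 - 6 * u
    d10 = 3 * u2 - 4 * u + 1
    d01 = -6 * u2 + 6 * u
    d11 = 3 * u2 - 2 * u
    return d00, d10, d01, d11


@dataclass
class SplineModel:
    """Fitted Catmull-Rom centerline.

    Attributes
    ----------
    control_points : ndarray, shape (N, 3)
        World-mm control points P_1..P_N (first = arc-length origin).
    d0 : ndarray, shape (3,)
        Unit reference direction defining theta = 0.
    n_scaled_tangents : bool
        If True, segment tangents are N*(P_{i+2}-P_i) instead of the standard
        Catmull-Rom (P_{i+2}-P_i)/2.
    """

    control_points: np.ndarray
    d0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    n_scaled_tangents: bool = False
    table_samples_per_segment: int = 128

    def __post_init__(self) -> None:
        P = np.asarray(self.control_points, dtype=float)
        if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
            raise GeometryError("need at least 4 distinct 3-D control points")
        if np.any(np.linalg.norm(np.diff(P, axis=0), axis=1) < 1e-12):
            raise GeometryError("consecutive control points coincide")
        self.control_points = P
        self.d0 = np.asarray(self.d0, dtype=float)
        n = np.linalg.norm(self.d0)
        if n < 1e-12:
            raise GeometryError("d0 must be a nonzero vector")
        self.d0 = self.d0 / n
        # ghost points: end tangents point at the adjacent control point
        self._ext = np.vstack([2 * P[0] - P[1], P, 2 * P[-1] - P[-2]])
        self._n_seg = P.shape[0] - 1
        self._build_table()
        # d0 must never be (near-)parallel to the tangent anywhere
        tans = self._tangents_at(self._table_t)
        if np.any(np.abs(tans @ self.d0) > 1.0 - 1e-6):
            raise GeometryError("d0 is parallel to the spline tangent")

    # -- evaluation ---------------------------------------------------------

    @property
    def n_control(self) -> int:
        return self.control_points.shape[0]

    def _segment(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        x = t * self._n_seg
        i = np.minimum(x.astype(int), self._n_seg - 1)
        return i, x - i

    def _tau(self) -> float:
        return float(self.n_control) if self.n_scaled_tangents else 0.5

    def evaluate(self, t) -> np.ndarray:
        """Position p(t) for t in [0, 1); scalar or array t."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any((t_arr < 0) | (t_arr >= 1 + 1e-12)):
            warnings.warn("t outside [0,1) clamped", stacklevel=2)
        i, u = self._segment(t_arr)
        C = self._ext
        tau = self._tau()
        A, B = C[i + 1], C[i + 2]
        m1 = tau * (C[i + 2] - C[i])
        m2 = tau * (C[i + 3] - C[i + 1])
        h00, h10, h01, h11 = _hermite(u)
        p = (h00[:, None] * A + h10[:, None] * m1
             + h01[:, None] * B + h11[:, None] * m2)
        return p[0] if np.isscalar(t) or np.ndim(t) == 0 else p

    def _derivative(self, t_arr: np.ndarray) -> np.ndarray:
        """dp/dt (not normalized)."""
        i, u = self._segment(t_arr)
        C = self._ext
        tau = self._tau()
        A, B = C[i + 1], C[i + 2]
        m1 = tau * (C[i + 2] - C[i])
        m2 = tau * (C[i + 3] - C[i + 1])
        d00, d10, d01, d11 = _hermite_d(u)
        dp_du = (d00[:, None] * A + d10[:, None] * m1
                 + d01[:, None] * B + d11[:, None] * m2)
        return dp_du * self._n_seg

    def _tangents_at(self, t_arr: np.ndarray) -> np.ndarray:
        d = self._derivative(np.atleast_1d(t_arr))
        n = np.linalg.norm(d, axis=1, keepdims=True)
        n[n < 1e-12] = 1.0
        return d / n

    def tangent(self, t) -> np.ndarray:
        """Unit tangent at t."""
        out = self._tangents_at(np.atleast_1d(np.asarray(t, dtype=float)))
        return out[0] if np.ndim(t) == 0 else out

    # -- arc length ---------------------------------------------------------

    def _build_table(self) -> None:
        m = self.table_samples_per_segment * self._n_seg
        t = np.linspace(0.0, 1.0, m + 1)
        speed = np.linalg.norm(self._derivative(t), axis=1)
        ds = np.concatenate(
            [[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2 * np.diff(t))]
        )
        self._table_t = t
        self._table_s = ds
        if np.any(np.diff(ds) <= 0):
            raise GeometryError("arc length is not strictly increasing")
        self._points = self.evaluate(t)
        self._tree = cKDTree(self._points)

    @property
    def total_length(self) -> float:
        """Total arc length in mm."""
        return float(self._table_s[-1])

    def arc_length(self, t) -> np.ndarray | float:
        """s(t): arc length in mm from the origin (t=0) to parameter t."""
        t_arr = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, 1.0)
        s = np.interp(t_arr, self._table_t, self._table_s)
        return float(s[0]) if np.ndim(t) == 0 else s

    def t_at_arc_length(self, z) -> np.ndarray | float:
        """Inverse of :meth:`arc_length` (clamped to the spline extent)."""
        z_arr = np.atleast_1d(np.asarray(z, dtype=float))
        if np.any((z_arr < -1e-9) | (z_arr > self.total_length + 1e-9)):
            raise GeometryError(
                f"arc length outside [0, {self.total_length:.3f}] mm"
            )
        t = np.interp(z_arr, self._table_s, self._table_t)
        return float(t[0]) if np.ndim(z) == 0 else t

    # -- cylindrical frame --------------------------------------------------

    def frame(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal frame (e1, e2, tangent) at t; e1 is the projection of
        d0 onto the plane orthogonal to the tangent, e2 = tangent x e1."""
        T = self.tangent(t)
        scalar = np.ndim(t) == 0
        T2 = np.atleast_2d(T)
        e1 = self.d0[None, :] - (T2 @ self.d0)[:, None] * T2
        n = np.linalg.norm(e1, axis=1, keepdims=True)
        if np.any(n < 1e-9):
            raise GeometryError("tangent parallel to d0; frame undefined")
        e1 = e1 / n
        e2 = np.cross(T2, e1)
        if scalar:
            return e1[0], e2[0], T2[0]
        return e1, e2, T2

    def nearest_t(self, x: np.ndarray) -> float:
        """Parameter t* of the spline point nearest to world point x,
        refined from the dense table by local quadratic interpolation."""
        x = np.asarray(x, dtype=float)
        _, k = self._tree.query(x)
        lo = max(k - 1, 0)
        hi = min(k + 1, len(self._table_t) - 1)
        if lo == hi:
            return float(self._table_t[k])
        # parabolic minimum of squared distance over the three neighbors
        ts = self._table_t[[lo, min(k, hi), hi]]
        if lo == k or hi == k:
            ts = self._table_t[lo:hi + 1]
            d2 = np.sum((self._points[lo:hi + 1] - x) ** 2, axis=1)
            return float(ts[np.argmin(d2)])
        d2 = np.sum((self._points[[lo, k, hi]] - x) ** 2, axis=1)
        denom = d2[0] - 2 * d2[1] + d2[2]
        if denom <= 1e-15:
            return float(self._table_t[k])
        shift = 0.5 * (d2[0] - d2[2]) / denom
        shift = np.clip(shift, -1.0, 1.0)
        return float(self._table_t[k] + shift * (self._table_t[1] - self._table_t[0]))

    def nearest_t_batch(self, xs: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`nearest_t` for an (M, 3) array of points."""
        xs = np.atleast_2d(np.asarray(xs, dtype=float))
        _, k = self._tree.query(xs)
        n = len(self._table_t)
        lo = np.clip(k - 1, 0, n - 1)
        hi = np.clip(k + 1, 0, n - 1)
        d2l = np.sum((self._points[lo] - xs) ** 2, axis=1)
        d2c = np.sum((self._points[k] - xs) ** 2, axis=1)
        d2h = np.sum((self._points[hi] - xs) ** 2, axis=1)
        denom = d2l - 2 * d2c + d2h
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (d2l - d2h) / denom
        shift = np.where((denom > 1e-15) & (lo != k) & (hi != k),
                         np.clip(shift, -1.0, 1.0), 0.0)
        step = self._table_t[1] - self._table_t[0]
        return np.clip(self._table_t[k] + shift * step, 0.0, 1.0)

    def euclid_to_cyl(self, x: np.ndarray) -> CylCoord:
        """Convert a world point to (z, theta, r) about this centerline."""
        x = np.asarray(x, dtype=float)
        t_star = self.nearest_t(x)
        p = self.evaluate(t_star)
        v = x - p
        r = float(np.linalg.norm(v))
        if r > CAPTURE_RADIUS_MM:
            raise GeometryError(
                f"point {x} at r={r:.1f} mm is outside the capture region"
            )
        eps = 1e-9
        if (t_star < eps or t_star > 1 - eps) and r > eps:
            T = self.tangent(t_star)
            axial = float(v @ T)
            if abs(axial) > 1e-6 * max(r, 1.0) + 1e-6:
                raise GeometryError(
                    f"point {x} projects beyond the spline end (t*={t_star:.3f})"
                )
        if r < 1e-12:
            return CylCoord(float(self.arc_length(t_star)), 0.0, 0.0)
        e1, e2, _ = self.frame(t_star)
        theta = float(np.arctan2(v @ e2, v @ e1)) % (2 * np.pi)
        return CylCoord(float(self.arc_length(t_star)), theta, r)

    def cyl_to_euclid(self, c: CylCoord) -> np.ndarray:
        """Convert (z, theta, r) back to a world point."""
        z, theta, r = c
        if r < 0:
            raise GeometryError("r must be nonnegative")
        t_star = self.t_at_arc_length(z)
        p = self.evaluate(t_star)
        e1, e2, _ = self.frame(t_star)
        return p + r * (np.cos(theta) * e1 + np.sin(theta) * e2)

    def project_arc_lengths(self, xs: np.ndarray) -> np.ndarray:
        """Arc lengths z of the nearest spline points for (M, 3) world points."""
        t = self.nearest_t_batch(xs)
        return np.interp(t, self._table_t, self._table_s)

    def point_at_world_z(self, zw: float) -> np.ndarray | None:
        """Spline point where the curve crosses the axial plane at world
        z-coordinate ``zw`` (None if the plane misses the spline). Assumes the
        curve's world z is monotone, which holds for a cord centerline."""
        pz = self._points[:, 2]
        if zw < pz.min() - 1e-9 or zw > pz.max() + 1e-9:
            return None
        order = np.argsort(pz)
        x = np.interp(zw, pz[order], self._points[order, 0])
        y = np.interp(zw, pz[order], self._points[order, 1])
        return np.array([x, y, zw])

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "control_points": self.control_points.tolist(),
                "d0": self.d0.tolist(),
                "n_scaled_tangents": self.n_scaled_tangents,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SplineModel":
        text = (Path(source).read_text()
                if Path(str(source)).exists() else str(source))
        obj = json.loads(text)
        return cls(
            control_points=np.asarray(obj["control_points"], dtype=float),
            d0=np.asarray(obj["d0"], dtype=float),
            n_scaled_tangents=bool(obj.get("n_scaled_tangents", False)),
        )


def fit_spline(markings: np.ndarray, n_control: int = 20,
               d0: np.ndarray | None = None,
               n_scaled_tangents: bool = False) -> SplineModel:
    """Fit the centerline spline from ordered user markings.

    An equally distributed subset of ``n_control`` markings becomes the
    control points (the first marking, the PMJ analog, is always kept as the
    arc-length origin). Fewer than ``n_control`` distinct markings: all are
    used with a warning (at least 4 required).
    """
    pts = np.atleast_2d(np.asarray(markings, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("markings must be an (M, 3) array of world points")
    # drop consecutive duplicates, preserving order
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if len(pts) < 4:
        raise GeometryError(
            f"need at least 4 distinct markings, got {len(pts)}"
        )
    if len(pts) < n_control:
        warnings.warn(
            f"only {len(pts)} distinct markings for {n_control} requested "
            "control points; using all of them",
            stacklevel=2,
        )
        ctrl = pts
    else:
        sel = np.round(np.linspace(0, len(pts) - 1, n_control)).astype(int)
        ctrl = pts[np.unique(sel)]
    kwargs = {} if d0 is None else {"d0": d0}
    return SplineModel(control_points=ctrl,
                       n_scaled_tangents=n_scaled_tangents, **kwargs)
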