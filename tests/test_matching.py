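"""Matching engine: NCC, threshold schedule, edge field operations,
rasterization, re-centering, and the end-to-end pipeline."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordseg.errors import GeometryError
from cordseg.io import Mask, gradient_magnitude, load_template_db, \
    save_template_db
from cordseg.matching import (FLAG_FALLBACK, FLAG_MATCHED, EdgeField,
                              SegmentOptions, find_matches, infer_edge,
                              interpolate_edge_field, match_batch, ncc,
                              rasterize_slice, recenter, segment,
                              smooth_edge_field)
from cordseg.metrics import dice
from cordseg.profiles import N_PROFILE, TemplateDB, slice_angles
from cordseg.spline import fit_spline


def _direct_ncc(f, t):
    """The printed formula, evaluated literally (population sigmas)."""
    f = np.asarray(f, float)
    t = np.asarray(t, float)
    n = len(f)
    fbar, tbar = f.mean(), t.mean()
    sf = np.sqrt(np.sum((f - fbar) ** 2) / n)
    st_ = np.sqrt(np.sum((t - tbar) ** 2) / n)
    return np.sum((f - fbar) * (t - tbar)) / n / (sf * st_)


class TestNCC:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=70)
        assert ncc(x, x) == pytest.approx(1.0, abs=1e-12)
        assert ncc(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        x = rng.normal(size=70)
        assert ncc(x, 3.7 * x + 11.0) == pytest.approx(1.0, abs=1e-12)
        assert ncc(2.0 * x - 5.0, x) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_integer_arrays_match_printed_formula(self):
        f = np.array([3, 1, 4, 1, 5, 9, 2, 6], dtype=float)
        t = np.array([2, 7, 1, 8, 2, 8, 1, 8], dtype=float)
        assert ncc(f, t) == pytest.approx(_direct_ncc(f, t), abs=1e-12)
        assert ncc(t, f) == pytest.approx(ncc(f, t), abs=1e-12)

    def test_constant_array_defined_as_zero(self):
        assert ncc(np.full(10, 3.0), np.arange(10.0)) == 0.0


def _db_from_values(values, edges=None):
    values = np.asarray(values, dtype=np.float32)
    n = len(values)
    edges = np.full(n, 30) if edges is None else np.asarray(edges)
    return TemplateDB(
        values=values,
        distances=np.tile(np.arange(N_PROFILE, dtype=np.float32) * 0.35,
                          (n, 1)),
        edge_index=edges,
        slice_index=np.zeros(n, dtype=np.int32),
        angle=np.zeros(n, dtype=np.float32),
        subject_idx=np.zeros(n, dtype=np.int32),
        subjects=["synthetic"],
    )


def _correlated_profile(base, target_ncc, rng):
    """A profile with a prescribed NCC to ``base`` (rotation in the
    mean-centered subspace)."""
    fc = base - base.mean()
    v = rng.normal(size=len(base))
    v -= v.mean()
    v -= (v @ fc) / (fc @ fc) * fc
    v *= np.linalg.norm(fc) / np.linalg.norm(v)
    phi = np.arccos(target_ncc)
    return fc * np.cos(phi) + v * np.sin(phi) + 5.0


class TestFindMatches:
    def test_exact_copies_match_at_threshold_one(self, rng):
        test = rng.normal(size=N_PROFILE)
        db = _db_from_values(np.tile(test, (60, 1)))
        m = find_matches(test, db)
        assert m.final_threshold == pytest.approx(1.0)
        assert len(m.template_indices) == 50
        np.testing.assert_allclose(m.ncc_values, 1.0, atol=1e-6)
        assert not m.fallback
        # ties broken by insertion order
        np.testing.assert_array_equal(m.template_indices, np.arange(50))

    def test_constructed_correlations_stop_at_098(self, rng):
        test = rng.normal(size=N_PROFILE)
        rows = [_correlated_profile(test, 0.985, rng) for _ in range(50)]
        rows += [_correlated_profile(test, 0.90, rng) for _ in range(30)]
        m = find_matches(test, _db_from_values(rows))
        assert m.final_threshold == pytest.approx(0.98)
        assert not m.fallback
        assert m.ncc_values.min() >= 0.98 - 1e-6

    def test_anticorrelated_db_triggers_fallback(self, rng):
        test = rng.normal(size=N_PROFILE)
        rows = [_correlated_profile(test, -0.5 + 0.01 * i, rng)
                for i in range(60)]
        m = find_matches(test, _db_from_values(rows))
        assert m.fallback
        assert len(m.template_indices) == 50
        assert m.final_threshold == pytest.approx(0.30)

    def test_small_db_warns_and_uses_all(self, rng):
        test = rng.normal(size=N_PROFILE)
        db = _db_from_values(rng.normal(size=(20, N_PROFILE)))
        with pytest.warns(UserWarning, match="only 20"):
            m = find_matches(test, db)
        assert len(m.template_indices) == 20

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_schedule_invariants(self, seed):
        rng = np.random.default_rng(seed)
        test = rng.normal(size=N_PROFILE)
        db = _db_from_values(rng.normal(size=(120, N_PROFILE)))
        m = find_matches(test, db)
        # final threshold lies on the schedule {1.00, 0.98, ..., 0.30}
        steps = np.round((1.0 - m.final_threshold) / 0.02)
        assert m.final_threshold == pytest.approx(1.0 - 0.02 * steps,
                                                  abs=1e-9)
        assert 0.30 - 1e-9 <= m.final_threshold <= 1.0 + 1e-9
        assert len(m.template_indices) == 50
        if not m.fallback:
            assert m.ncc_values.min() >= m.final_threshold - 1e-6
        assert m.inferred_edge == pytest.approx(
            np.mean([30] * 50))  # all edges 30 in this db


class TestInferEdge:
    def test_mean_of_edges(self, rng):
        test = rng.normal(size=N_PROFILE)
        db = _db_from_values(np.tile(test, (2, 1)), edges=[10, 20])
        with pytest.warns(UserWarning):
            m = find_matches(test, db)
        assert infer_edge(m) == pytest.approx(15.0)

    def test_random_edges_equal_numpy_mean(self, rng):
        test = rng.normal(size=N_PROFILE)
        edges = rng.integers(0, 70, size=60)
        db = _db_from_values(np.tile(test, (60, 1)), edges=edges)
        m = find_matches(test, db)
        expected = edges[np.asarray(m.template_indices)].mean()
        assert infer_edge(m) == pytest.approx(expected)


def _field(mm, pos, flags=None):
    mm = np.asarray(mm, dtype=float)
    idx = np.clip(mm / 0.35, 0, N_PROFILE - 1)
    flags = (np.full(mm.shape, FLAG_MATCHED, dtype=np.uint8)
             if flags is None else flags)
    centers = np.zeros((mm.shape[0], 3))
    centers[:, 2] = np.asarray(pos) * 0.3
    centers[:, :2] = 9.3
    return EdgeField(mm=mm, index=idx, flags=flags,
                     axial_pos=np.asarray(pos, dtype=float), centers=centers)


@pytest.fixture
def straight_spline():
    pts = np.outer(np.linspace(0, 23.7, 30), [0, 0, 1.0]) + [9.3, 9.3, 0.0]
    return fit_spline(pts, n_control=20)


class TestInterpolateEdgeField:
    def test_constant_brackets_fill_constant(self, straight_spline,
                                             clean_case):
        sparse = _field(np.full((2, 179), 4.0), [0, 10])
        full = interpolate_edge_field(sparse, 79, straight_spline,
                                      clean_case.volume)
        assert full.n_slices == 11
        np.testing.assert_allclose(full.mm, 4.0)

    def test_linear_midpoint(self, straight_spline, clean_case):
        sparse = _field(np.stack([np.full(179, 10 * 0.35),
                                  np.full(179, 20 * 0.35)]), [0, 10])
        full = interpolate_edge_field(sparse, 79, straight_spline,
                                      clean_case.volume)
        np.testing.assert_allclose(full.index[5], 15.0, atol=1e-9)

    def test_matches_piecewise_linear_oracle(self, rng, straight_spline,
                                             clean_case):
        pos = np.array([3.0, 17.0, 31.0, 50.0])
        mm = rng.uniform(2, 6, size=(4, 179))
        full = interpolate_edge_field(_field(mm, pos), 79, straight_spline,
                                      clean_case.volume)
        for r, j in enumerate(full.axial_pos):
            for a in (0, 45, 178):
                seg = np.searchsorted(pos, j, side="right") - 1
                seg = min(max(seg, 0), 2)
                w = (j - pos[seg]) / (pos[seg + 1] - pos[seg])
                expected = (1 - w) * mm[seg, a] + w * mm[seg + 1, a]
                assert full.mm[r, a] == pytest.approx(expected, abs=1e-9)

    def test_no_extrapolation_beyond_stations(self, straight_spline,
                                              clean_case):
        sparse = _field(np.full((2, 179), 4.0), [10.2, 30.7])
        full = interpolate_edge_field(sparse, 79, straight_spline,
                                      clean_case.volume)
        assert full.axial_pos[0] == 11
        assert full.axial_pos[-1] == 30

    def test_single_station_rejected(self, straight_spline, clean_case):
        with pytest.raises(GeometryError):
            interpolate_edge_field(_field(np.full((1, 179), 4.0), [0]), 79,
                                   straight_spline, clean_case.volume)


class TestSmoothEdgeField:
    def test_constant_field_unchanged(self):
        f = _field(np.full((20, 179), 4.0), np.arange(20))
        out = smooth_edge_field(f)
        np.testing.assert_allclose(out.mm, 4.0)

    def test_single_spike_removed(self):
        mm = np.full((20, 179), 4.0)
        mm[10, 90] = 20.0
        out = smooth_edge_field(_field(mm, np.arange(20)), kernels=(5,))
        np.testing.assert_allclose(out.mm, 4.0)

    def test_angular_median_matches_sliding_window_oracle(self, rng):
        mm = rng.uniform(1, 8, size=(3, 179))
        f = _field(mm, np.arange(3))
        # single kernel, theta pass only is the first stage; reproduce both
        out = smooth_edge_field(f, kernels=(5,))
        stage1 = np.empty_like(mm)
        for s in range(3):
            for a in range(179):
                win = [mm[s, (a + d) % 179] for d in range(-2, 3)]
                stage1[s, a] = np.median(win)
        stage2 = np.empty_like(mm)
        # half-sample reflect padding (edge row duplicated), window 5
        padded = np.vstack([stage1[1::-1], stage1, stage1[:-3:-1]])
        for s in range(3):
            for a in range(179):
                stage2[s, a] = np.median(padded[s:s + 5, a])
        np.testing.assert_allclose(out.mm, stage2, atol=1e-12)

    def test_even_kernel_rejected(self):
        f = _field(np.full((6, 179), 4.0), np.arange(6))
        with pytest.raises(ValueError):
            smooth_edge_field(f, kernels=(4,))


class TestRasterizeSlice:
    def test_constant_edge_yields_disk(self, clean_case):
        vol = clean_case.volume
        center = vol.voxel_to_world(np.array([31.0, 31.0, 5.0]))
        r = 4.0
        sl = rasterize_slice(center, slice_angles(), np.full(179, r), vol, 5)
        area = sl.sum() * vol.spacing[0] * vol.spacing[1]
        perim_band = 2 * np.pi * r * float(np.max(vol.spacing[:2]))
        assert abs(area - np.pi * r ** 2) <= perim_band

    def test_zero_edges_empty(self, clean_case):
        vol = clean_case.volume
        center = vol.voxel_to_world(np.array([31.0, 31.0, 5.0]))
        sl = rasterize_slice(center, slice_angles(), np.zeros(179), vol, 5)
        assert sl.sum() == 0

    def test_elliptical_edge_matches_pointwise_oracle(self, clean_case):
        vol = clean_case.volume
        center = vol.voxel_to_world(np.array([31.0, 31.0, 5.0]))
        ang = slice_angles()
        a_ax, b_ax = 5.0, 3.0
        th = np.deg2rad(ang)
        edges = a_ax * b_ax / np.sqrt((b_ax * np.cos(th)) ** 2
                                      + (a_ax * np.sin(th)) ** 2)
        sl = rasterize_slice(center, ang, edges, vol, 5)
        nx, ny, _ = vol.shape
        for i in range(0, nx, 3):
            for j in range(0, ny, 3):
                w = vol.voxel_to_world(np.array([float(i), float(j), 5.0]))
                dx, dy = w[0] - center[0], w[1] - center[1]
                r = np.hypot(dx, dy)
                phi = np.degrees(np.arctan2(dy, dx)) % 360.0
                k = int(phi // 2.0)
                if k >= 178:  # wrap segment between 356 deg and 360 deg
                    a0, a1 = 356.0, 360.0
                    e0, e1 = edges[178], edges[0]
                else:
                    a0, a1 = ang[k], ang[k + 1]
                    e0, e1 = edges[k], edges[k + 1]
                lim = e0 + (phi - a0) / (a1 - a0) * (e1 - e0)
                assert sl[i, j] == (r <= lim)

    def test_star_convex_along_polar_scan(self, clean_case, rng):
        vol = clean_case.volume
        center = vol.voxel_to_world(np.array([31.0, 31.0, 5.0]))
        # smooth lobed boundary: slope bounded so voxel jitter cannot flip
        # inclusion far from the true boundary
        th = np.deg2rad(slice_angles())
        edges = 4.0 + 0.8 * np.sin(3 * th) + 0.4 * np.cos(5 * th)
        sl = rasterize_slice(center, slice_angles(), edges, vol, 5)
        inv = np.linalg.inv(vol.affine)
        diag = float(np.linalg.norm(vol.spacing[:2]))
        for phi in np.deg2rad(np.arange(0, 360, 15)):
            d = np.array([np.cos(phi), np.sin(phi), 0.0])
            r_in, r_out = [], []
            for r in np.arange(0.0, 10.0, 0.05):
                p = center + r * d
                v = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
                (r_in if sl[v[0], v[1]] else r_out).append(r)
            # star-convex up to voxelization: once the scan leaves the
            # region it may only re-enter within one voxel diagonal
            if r_in and r_out:
                assert max(r_in) <= min(r_out) + diag


class TestRecenter:
    def test_refined_spline_has_500_control_points(self, clean_case):
        sp = recenter(clean_case.truth_mask)
        assert sp.n_control == 500

    def test_cylinder_centroids_recover_axis(self, clean_case):
        sp = recenter(clean_case.truth_mask)
        truth = clean_case.truth_centerline
        # already-centered mask: recentering reproduces the axis closely
        for z in (3.0, 11.0, 20.0):
            p = sp.point_at_world_z(z)
            assert np.hypot(p[0] - truth[0, 0], p[1] - truth[0, 1]) < 0.1 * \
                np.max(clean_case.volume.spacing)

    def test_curved_mask_centerline_within_half_voxel(self, curved_case):
        sp = recenter(curved_case.truth_mask)
        cfg = curved_case.config
        for z in (4.0, 12.0, 19.0):
            p = sp.point_at_world_z(z)
            c = cfg.center_at(z)[0]
            assert np.hypot(p[0] - c[0], p[1] - c[1]) < 0.5 * np.max(
                cfg.voxel_spacing)

    def test_too_few_slices_rejected(self, clean_case):
        data = np.zeros_like(clean_case.truth_mask.data)
        data[30:33, 30:33, 5] = 1
        m = Mask(data=data, spacing=clean_case.volume.spacing,
                 affine=clean_case.volume.affine)
        with pytest.raises(GeometryError):
            recenter(m)


@pytest.fixture(scope="module")
def self_segmentation(clean_case, clean_db):
    opts = SegmentOptions(n_slices=40)
    return segment(clean_case.volume, clean_case.truth_centerline, clean_db,
                   opts), opts


class TestSegmentPipeline:
    def test_self_segmentation_reproduces_truth(self, clean_case,
                                                self_segmentation):
        res, _ = self_segmentation
        assert dice(res.mask, clean_case.truth_mask) >= 0.98
        matched = res.station_field.flags & FLAG_MATCHED
        assert matched.all()
        assert res.meta["n_fallback"] == 0

    def test_deterministic_and_db_roundtrip_identical(self, tmp_path,
                                                      clean_case, clean_db,
                                                      self_segmentation):
        res, opts = self_segmentation
        p = tmp_path / "db.h5"
        save_template_db(clean_db, p)
        res2 = segment(clean_case.volume, clean_case.truth_centerline,
                       load_template_db(p), opts)
        np.testing.assert_array_equal(res.mask.data, res2.mask.data)
        np.testing.assert_allclose(res.refined_spline.control_points,
                                   res2.refined_spline.control_points)

    def test_smoothing_barely_changes_clean_phantom(self, clean_case,
                                                    clean_db,
                                                    self_segmentation):
        res, opts = self_segmentation
        res_s = segment(clean_case.volume, clean_case.truth_centerline,
                        clean_db, dataclasses.replace(opts, smooth=True))
        changed = int(np.sum(res.mask.data != res_s.mask.data))
        assert changed < 0.01 * clean_case.truth_mask.n_voxels

    def test_refined_spline_lies_inside_mask(self, self_segmentation,
                                             clean_case):
        res, _ = self_segmentation
        pts = res.refined_spline.control_points
        vox = np.rint(res.mask.world_to_voxel(pts)).astype(int)
        assert res.mask.data[vox[:, 0], vox[:, 1], vox[:, 2]].all()
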