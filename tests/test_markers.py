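"""Multi-scale marker model: patterns, schedules, rendering, floor mapping."""

import numpy as np
import pytest

from msmcal.exceptions import ScheduleError
from msmcal.geometry import Homography, apply_homography
from msmcal.markers import (
    DEFAULT_SCALES,
    MSMSpec,
    PatternSpec,
    default_dictionary,
    default_floor_homography,
    floor_coordinates,
    make_msm,
    make_schedule,
    render_projector_frame,
)


class TestDictionary:
    def test_rotation_safe_decoding(self):
        d = default_dictionary()
        rng = np.random.default_rng(0)
        for sid in rng.choice(d.safe_ids, size=40, replace=False):
            g = d.bit_grid(int(sid))[1:-1, 1:-1]
            for rot in range(4):
                res = d.decode(np.rot90(g, k=-rot))
                assert res is not None
                assert res[0] == sid

    def test_payload_never_degenerate(self):
        d = default_dictionary()
        for sid in (d.safe_ids[0], d.safe_ids[-1], d.safe_ids[len(d.safe_ids) // 2]):
            bits = d.bit_grid(int(sid))[1:-1, 1:-1]
            assert 5 <= bits.sum() <= 20

    def test_garbage_rejected(self):
        d = default_dictionary()
        assert d.decode(np.zeros((5, 5), dtype=np.uint8)) is None
        assert d.decode(np.ones((5, 5), dtype=np.uint8)) is None


class TestMakeMsm:
    def test_singleton_scale_set(self):
        msm = make_msm(PatternSpec(), [100.0, 200.0], scales=(1.0,))
        assert msm.scales == (1.0,)
        assert np.allclose(msm.instance_corners(0, 40.0), PatternSpec().corners(40.0, [100, 200]))

    def test_physical_sizes_5cm_to_40cm(self):
        """Seven scale factors on a 5 cm base span 5 cm ... 40 cm."""
        msm = make_msm(PatternSpec(base_side=0.05), [0, 0], scales=DEFAULT_SCALES)
        sides = msm.side_lengths_m()
        assert np.allclose(sides[0], 0.05)
        assert np.allclose(sides[-1], 0.40)
        assert np.allclose(sides, [0.05, 0.07, 0.10, 0.15, 0.20, 0.30, 0.40])

    def test_center_fixed_point_100_random(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(0, 1920, size=2)
            lams = np.sort(rng.uniform(0.2, 10, size=4))
            msm = make_msm(PatternSpec(), p, scales=tuple(lams))
            for s in range(4):
                corners = msm.instance_corners(s, 50.0)
                center = corners.mean(axis=0)  # square: centroid == center
                assert np.allclose(center, p, atol=1e-9)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            make_msm(PatternSpec(), [0, 0], scales=(1.0, -2.0))


class TestSchedule:
    def test_default_schedule_has_3200_distinct_centers(self):
        sched = make_schedule()
        centers = sched.centers()
        assert len(centers) == 3200
        assert len({tuple(c) for c in centers}) == 3200

    def test_single_array_is_base_grid(self):
        sched = make_schedule(n_arrays=1, markers_per_array=8, grid_shape=(4, 2))
        assert sched.n_arrays == 1
        assert len(sched.all_markers()) == 8

    def test_marker_id_encodes_array_and_index(self):
        sched = make_schedule(n_arrays=5, markers_per_array=8, grid_shape=(4, 2))
        for a, arr in enumerate(sched.arrays):
            for w, m in enumerate(arr):
                assert m.marker_id == a * 8 + w

    def test_all_centers_inside_projector_image(self):
        sched = make_schedule()
        W, H = sched.projector_resolution
        c = sched.centers()
        assert (c[:, 0] > 0).all() and (c[:, 0] < W).all()
        assert (c[:, 1] > 0).all() and (c[:, 1] < H).all()

    def test_id_center_bijection(self):
        sched = make_schedule(n_arrays=9, markers_per_array=8, grid_shape=(4, 2))
        ids = [m.marker_id for m in sched.all_markers()]
        centers = {m.marker_id: m.center_p for m in sched.all_markers()}
        assert sorted(ids) == list(range(72))
        assert len(set(centers.values())) == 72

    def test_grid_shape_mismatch_rejected(self):
        with pytest.raises(ScheduleError):
            make_schedule(n_arrays=2, markers_per_array=10, grid_shape=(4, 2))


class TestRendering:
    @pytest.fixture(scope="class")
    def small_schedule(self):
        return make_schedule(
            n_arrays=4, markers_per_array=8, grid_shape=(4, 2),
            base_px=40.0, margin_px=200.0,
        )

    def test_base_scale_pixel_size(self, small_schedule):
        img, meta = render_projector_frame(small_schedule, 0, 0)
        for m in meta:
            c = m["corners"]
            assert np.allclose(c[1, 0] - c[0, 0], 40.0)
            assert np.allclose(c[3, 1] - c[0, 1], 40.0)

    def test_rendered_center_matches_stored(self, small_schedule):
        """Rasterize then re-measure: symbol quad centroid within 0.5 px."""
        img, meta = render_projector_frame(small_schedule, 1, 3)
        from msmcal.detection import center_from_corners, detect_frame

        dets = detect_frame(img)
        bysym = {m["symbol_id"]: m for m in meta}
        assert len(dets) == 8
        for d in dets:
            c = center_from_corners(d.corners)
            assert np.linalg.norm(c - np.array(bysym[d.symbol_id]["center"])) < 0.5

    def test_consecutive_arrays_shift_by_offset(self, small_schedule):
        img0, m0 = render_projector_frame(small_schedule, 0, 1)
        img1, m1 = render_projector_frame(small_schedule, 1, 1)
        off = small_schedule.array_offsets[1] - small_schedule.array_offsets[0]
        for a, b in zip(m0, m1):
            assert np.allclose(np.array(b["center"]) - np.array(a["center"]), off)

    def test_clipped_flagging(self):
        sched = make_schedule(
            n_arrays=1, markers_per_array=8, grid_shape=(4, 2),
            base_px=40.0, margin_px=0.0, scales=(1.0, 16.0),
        )
        _, meta = render_projector_frame(sched, 0, 1)
        assert any(m["clipped"] for m in meta)


class TestFloorCoordinates:
    def test_identity_map_embeds_at_z0(self):
        sched = make_schedule(n_arrays=2, markers_per_array=8, grid_shape=(4, 2))
        pts = floor_coordinates(sched, Homography(np.eye(3)))
        centers = sched.centers()
        for (mid, X), c in zip(pts, centers):
            assert np.allclose(X[:2], c)
            assert X[2] == 0.0

    def test_matches_direct_homography(self):
        sched = make_schedule(n_arrays=2, markers_per_array=8, grid_shape=(4, 2))
        G = np.array([[0.002, 1e-4, -1.9], [5e-5, -0.0021, 1.1], [1e-6, -2e-6, 1.0]])
        pts = floor_coordinates(sched, Homography(G))
        Gn = Homography(G).matrix
        for mid, X in pts:
            m = [mm for mm in sched.all_markers() if mm.marker_id == mid][0]
            direct = apply_homography(Gn, np.asarray(m.center_p))
            assert np.linalg.norm(X[:2] - direct) < 1e-10
            assert X[2] == 0.0

    def test_default_floor_homography_flips_v(self):
        sched = make_schedule(n_arrays=1, markers_per_array=8, grid_shape=(4, 2))
        G = default_floor_homography(sched, px_per_meter=800.0)
        top = apply_homography(G.matrix, np.array([960.0, 0.0]))
        bottom = apply_homography(G.matrix, np.array([960.0, 1080.0]))
        assert top[1] > bottom[1]  # image-down maps to -Y

    def test_singular_homography_rejected(self):
        sched = make_schedule(n_arrays=1, markers_per_array=8, grid_shape=(4, 2))
        with pytest.raises(ValueError):
            floor_coordinates(sched, np.diag([1.0, 1.0, 0.0]))
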