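"""LVG construction: contour splitting, deflection profiles, assembly,
rendering, the PVG baseline and the medial-position mapping."""

import numpy as np
import pytest

from laryngovibro import (
    LabelMaskSequence,
    assemble_from_geometry,
    assemble_lvg,
    build_pvg,
    deflection_profile,
    extract_contours,
    generate_sequence,
    map_pvg_medial_position,
    point_segment_distance,
    render_lvg,
    split_and_orient,
)
from laryngovibro.builder import (
    DegenerateContourError,
    FoldEdgeContour,
    LVGMatrix,
    UndefinedPositionError,
    prepare_landmarks,
)
from laryngovibro.io_masks import GLOTTIS, LEFT_VF, RIGHT_VF, ContourSet
from laryngovibro.landmarks import LandmarkTrack
from laryngovibro.synthetic import polyp_spec, symmetric_spec


class TestPointSegmentDistance:
    def test_perpendicular_foot_interior(self):
        d, off = point_segment_distance(np.array([[50.0, 30.0]]),
                                        np.array([0.0, 0.0]),
                                        np.array([100.0, 0.0]))
        assert d[0] == pytest.approx(30.0)
        assert abs(off[0]) == pytest.approx(30.0)

    def test_endpoint_regime(self):
        d, _ = point_segment_distance(np.array([[110.0, 30.0]]),
                                      np.array([0.0, 0.0]),
                                      np.array([100.0, 0.0]))
        assert d[0] == pytest.approx(np.hypot(10.0, 30.0), abs=1e-9)

    def test_point_on_axis_is_zero(self):
        d, off = point_segment_distance(np.array([[40.0, 0.0]]),
                                        np.array([0.0, 0.0]),
                                        np.array([100.0, 0.0]))
        assert d[0] == 0.0
        assert off[0] == 0.0

    def test_matches_dense_brute_force(self):
        """Closed-form segment distance equals dense minimization over the
        continuous axis parameter."""
        rng = np.random.default_rng(12345)
        kappa = np.linspace(0.0, 1.0, 100_000)[:, None]
        worst = 0.0
        for _ in range(60):
            a = rng.uniform(-40, 40, 2)
            b = rng.uniform(-40, 40, 2)
            if np.allclose(a, b):
                continue
            pts = rng.uniform(-60, 60, (8, 2))
            d, _ = point_segment_distance(pts, a, b)
            dense = a + kappa * (b - a)
            for k, p in enumerate(pts):
                brute = np.min(np.linalg.norm(dense - p, axis=1))
                worst = max(worst, abs(brute - d[k]))
        assert worst < 1e-3


class TestSplitAndOrient:
    def test_rectangle_medial_side(self):
        # left-fold rectangle, medial side faces larger columns
        contour = np.array([[0.0, 0.0], [0.0, 10.0], [30.0, 10.0],
                            [30.0, 0.0]])
        P = np.array([0.0, 10.0])
        A = np.array([30.0, 10.0])
        edge = split_and_orient(contour, P, A, side="left")
        np.testing.assert_allclose(edge.points[0], P)
        np.testing.assert_allclose(edge.points[-1], A)
        assert np.all(edge.points[:, 1] == 10.0)  # the medial side

    def test_degenerate_cut_raises(self):
        contour = np.array([[0.0, 0.0], [0.0, 10.0], [30.0, 10.0],
                            [30.0, 0.0]])
        with pytest.raises(DegenerateContourError):
            split_and_orient(contour, np.array([0.0, 10.0]),
                             np.array([0.1, 9.9]), side="left")

    def test_bulge_apex_on_medial_arc(self, symmetric_bundle):
        """The retained arc of a bulged fold contains the bulge apex
        (the most medial excursion recorded by the generator)."""
        seq = symmetric_bundle["seq"]
        lm = symmetric_bundle["lm"]
        gaw = symmetric_bundle["gaw"]
        t = int(np.argmax(gaw.values))  # maximally open frame
        cs = extract_contours(seq, t)
        edge = split_and_orient(cs.left_vf_contour, lm.P_l[t], lm.A[t], "left", t)
        apex_col = cs.left_vf_contour[:, 1].max()  # most medial = largest col
        assert edge.points[:, 1].max() == pytest.approx(apex_col, abs=1e-9)

    def test_symmetric_folds_are_mirror_images(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5:35, 8:19] = LEFT_VF
        frame[5:35, 21:32] = RIGHT_VF
        frame[5:35, 19:21] = GLOTTIS
        seq = LabelMaskSequence(frame[None], 4000.0)
        cs = extract_contours(seq, 0)
        P_l, A_l = np.array([5.0, 18.5]), np.array([34.0, 18.5])
        P_r, A_r = np.array([5.0, 21.5]), np.array([34.0, 21.5])
        e_l = split_and_orient(cs.left_vf_contour, P_l, A_l, "left")
        e_r = split_and_orient(cs.right_vf_contour, P_r, A_r, "right")
        mirrored = e_r.points.copy()
        mirrored[:, 1] = 39.0 - mirrored[:, 1]

        # the arcs mirror each other: same medial line, same extent (exact
        # vertex lists may differ by half-pixel corner vertices at the cut,
        # since traversal orientation flips under mirroring)
        for arc in (e_l.points, mirrored):
            interior = arc[(arc[:, 0] > 6) & (arc[:, 0] < 33)]
            np.testing.assert_allclose(interior[:, 1], 18.5, atol=1e-9)
        assert e_l.points[:, 0].min() == pytest.approx(
            mirrored[:, 0].min(), abs=1.0)
        assert e_l.points[:, 0].max() == pytest.approx(
            mirrored[:, 0].max(), abs=1.0)


class TestDeflectionProfile:
    def _edge(self, pts):
        return FoldEdgeContour(points=np.asarray(pts, float), side="left")

    def test_normalization_and_sign(self):
        # axis along +row; points at +col lie on the negative-cross side,
        # declared lateral here via lateral_sign=-1
        P, A = np.array([0.0, 0.0]), np.array([100.0, 0.0])
        edge = self._edge([[0.0, 0.0], [50.0, 30.0], [100.0, 0.0]])
        delta, _ = deflection_profile(edge, P, A, lateral_sign=-1.0)
        assert delta.shape == (256,)
        # apex interpolated on the 256-point arc-length grid
        assert delta.max() == pytest.approx(0.30, abs=3e-3)
        delta_neg, _ = deflection_profile(edge, P, A, lateral_sign=1.0)
        assert delta_neg.min() == pytest.approx(-0.30, abs=3e-3)

    def test_on_axis_points_zero(self):
        P, A = np.array([0.0, 0.0]), np.array([100.0, 0.0])
        edge = self._edge([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        delta, _ = deflection_profile(edge, P, A)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_endpoint_regime_distance(self):
        P, A = np.array([0.0, 0.0]), np.array([100.0, 0.0])
        edge = self._edge([[0.0, 0.0], [110.0, 30.0]])
        delta, _ = deflection_profile(edge, P, A, lateral_sign=-1.0)
        assert delta[-1] == pytest.approx(np.hypot(10, 30) / 100.0, abs=1e-6)


class TestAssembly:
    def test_matrix_shape_512_rows(self, symmetric_bundle):
        M = symmetric_bundle["lvg"]
        assert M.D.shape == (512, symmetric_bundle["seq"].n_frames)

    def test_static_scene_columns_identical(self):
        frame = np.zeros((64, 64), dtype=np.uint8)
        frame[8:56, 10:31] = LEFT_VF
        frame[8:56, 33:54] = RIGHT_VF
        frame[8:56, 31:33] = GLOTTIS
        seq = LabelMaskSequence(np.repeat(frame[None], 160, axis=0), 4000.0)
        M = assemble_lvg(seq)
        assert np.ptp(M.D, axis=1).max() < 1e-12
        # mirror-symmetric static scene: halves equal
        np.testing.assert_allclose(M.D[:256], M.D[256:], atol=5e-3)

    def test_scale_and_rotation_invariance(self, symmetric_bundle):
        seq = symmetric_bundle["seq"]
        lm = symmetric_bundle["lm"]
        n = 150
        contours = [extract_contours(seq, t) for t in range(n)]
        lm_n = LandmarkTrack(lm.P_r[:n], lm.P_l[:n], lm.A[:n], True)
        M0 = assemble_from_geometry(contours, lm_n, seq.fps)

        def rebuild(fn):
            cs2 = [ContourSet(fn(c.glottis_contour), fn(c.left_vf_contour),
                              fn(c.right_vf_contour), c.frame_index)
                   for c in contours]
            lm2 = LandmarkTrack(fn(lm_n.P_r), fn(lm_n.P_l), fn(lm_n.A), True)
            return assemble_from_geometry(cs2, lm2, seq.fps)

        M_scaled = rebuild(lambda a: 3.0 * a)
        assert np.abs(M_scaled.D - M0.D).max() < 1e-3
        th = 0.41
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        M_rot = rebuild(lambda a: a @ R.T + np.array([11.0, -4.0]))
        assert np.abs(M_rot.D - M0.D).max() < 1e-3

    def test_mirror_swap_exchanges_halves(self):
        seq, _ = generate_sequence(symmetric_spec(1, n_frames=150))
        M1 = assemble_lvg(seq)
        flipped = seq.frames[:, :, ::-1].copy()
        swapped = flipped.copy()
        swapped[flipped == LEFT_VF] = RIGHT_VF
        swapped[flipped == RIGHT_VF] = LEFT_VF
        M2 = assemble_lvg(LabelMaskSequence(swapped, seq.fps))
        np.testing.assert_array_equal(M1.D[:256], M2.D[256:])
        np.testing.assert_array_equal(M1.D[256:], M2.D[:256])

    def test_save_load_round_trip(self, tmp_path, symmetric_bundle):
        M = symmetric_bundle["lvg"]
        path = tmp_path / "lvg.npz"
        M.save(path)
        back = LVGMatrix.load(path)
        np.testing.assert_array_equal(back.D, M.D)
        assert back.fps == M.fps
        np.testing.assert_array_equal(back.gap, M.gap)


class TestRendering:
    def test_png_written(self, tmp_path, symmetric_bundle):
        out = tmp_path / "lvg.png"
        render_lvg(symmetric_bundle["lvg"], out)
        assert out.exists() and out.stat().st_size > 0

    def test_zero_matrix_renders_uniform_midtone(self, tmp_path):
        from PIL import Image

        M = LVGMatrix(D=np.zeros((512, 64)), fps=4000.0)
        out = tmp_path / "zero.png"
        render_lvg(M, out)
        img = np.asarray(Image.open(out).convert("RGB"), dtype=float)
        # the plot area is uniform: many pixels share one dominant colour
        colors, counts = np.unique(img.reshape(-1, 3), axis=0,
                                   return_counts=True)
        assert counts.max() > 0.2 * img.shape[0] * img.shape[1]


class TestPVG:
    def test_symmetric_lens_halves_equal(self, symmetric_bundle):
        P = build_pvg(symmetric_bundle["seq"], symmetric_bundle["lm"])
        assert P.D.shape[0] == 512
        assert np.abs(P.D[:256] - P.D[256:]).max() < 0.01

    def test_closed_frames_are_zero_columns(self, symmetric_bundle):
        P = build_pvg(symmetric_bundle["seq"], symmetric_bundle["lm"])
        closed = symmetric_bundle["gaw"].values == 0
        assert closed.any()
        assert np.allclose(P.D[:, closed], 0.0)

    def test_lens_medial_value_matches_geometry(self):
        """Static lens glottis: the medial PVG value equals the half-width
        over the glottal axis length."""
        h, w = 128, 64
        frame = np.zeros((h, w), dtype=np.uint8)
        rows = np.arange(14, 114)
        g_len = 99.0
        half = 8.0 * np.sin(np.pi * (rows - 14) / g_len)
        for r, g in zip(rows, half):
            gi = int(round(g))
            frame[r, 16:32 - gi] = LEFT_VF
            frame[r, 32 + gi:48] = RIGHT_VF
            if gi:
                frame[r, 32 - gi:32 + gi] = GLOTTIS
        seq = LabelMaskSequence(np.repeat(frame[None], 160, axis=0), 4000.0)
        P = build_pvg(seq)
        medial = P.D[128, 0]
        assert medial == pytest.approx(8.0 / g_len, rel=0.1)

    def test_medial_position_centered_opening(self, symmetric_bundle):
        P = build_pvg(symmetric_bundle["seq"], symmetric_bundle["lm"])
        p = map_pvg_medial_position(P, symmetric_bundle["axes"],
                                    symmetric_bundle["gaw"].values)
        assert p == pytest.approx(0.5, abs=0.03)

    def test_medial_position_polyp_below_half(self, polyp_bundle):
        P = build_pvg(polyp_bundle["seq"], polyp_bundle["lm"])
        p = map_pvg_medial_position(P, polyp_bundle["axes"],
                                    polyp_bundle["gaw"].values)
        assert p < 0.4  # ventral half blocked by the lesion

    def test_never_open_raises(self):
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5:35, 10:20] = LEFT_VF
        frame[5:35, 20:30] = RIGHT_VF
        seq = LabelMaskSequence(np.repeat(frame[None], 160, axis=0), 4000.0)
        lm, axes, gaw = prepare_landmarks(seq)
        P = build_pvg(seq, lm)
        with pytest.raises(UndefinedPositionError):
            map_pvg_medial_position(P, axes, gaw.values)
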