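"""Tests of line-profile extraction, FWHM and double-wall detection."""

import numpy as np
import pytest

from zctexture.image import ImagePlane
from zctexture.profiles import (
    detect_double_wall,
    extract_profile,
    fwhm,
    minmax_normalize,
    perpendicular_probe_line,
    probe_line_for_scene,
)
from zctexture.synthetic import SceneConfig, generate_scene

PX = 0.04  # SIM-like sampling used throughout these tests (um/px)


def dw_scene(seed):
    return generate_scene(
        SceneConfig(
            texture_class="double_wall", char_length_um=0.2, pixel_size_um=PX,
            density=0.2, seed=seed,
        )
    )


def ridge_scene(seed):
    return generate_scene(
        SceneConfig(
            texture_class="linear_cidc", char_length_um=0.2, pixel_size_um=PX,
            density=0.2, seed=seed,
        )
    )


class TestExtractProfile:
    def test_constant_channel_gives_constant_profile(self):
        planes = {"a": ImagePlane(np.full((64, 64), 3.0), PX)}
        prof = extract_profile(planes, (10, 10), (50, 40))
        assert np.allclose(prof.per_channel_values["a"], 3.0)

    def test_width_one_px_equals_single_line(self):
        rng = np.random.default_rng(0)
        planes = {"a": ImagePlane(rng.random((64, 64)), PX)}
        wide = extract_profile(planes, (5, 5), (60, 50), line_width_um=PX)
        from zctexture.image import bilinear_sample

        p0, p1 = np.array([5.0, 5.0]), np.array([60.0, 50.0])
        L = np.hypot(*(p1 - p0))
        t = np.linspace(0, L, int(L) + 1)
        u = (p1 - p0) / L
        pts = p0[None] + t[:, None] * u[None]
        direct = bilinear_sample(planes["a"].data, pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(wide.per_channel_values["a"], direct)

    def test_geometry_identical_across_channels(self):
        rng = np.random.default_rng(1)
        data = rng.random((64, 64))
        planes = {"a": ImagePlane(data, PX), "b": ImagePlane(data.copy(), PX)}
        prof = extract_profile(planes, (3, 8), (55, 44))
        np.testing.assert_array_equal(prof.per_channel_values["a"], prof.per_channel_values["b"])

    def test_ridge_peak_at_known_crossing(self):
        """A profile across a truth centreline peaks at the crossing point."""
        scene = ridge_scene(2)
        p0, p1 = probe_line_for_scene(scene, length_um=1.0)
        prof = extract_profile(scene.channels, p0, p1, line_width_um=0.2)
        peak_pos = prof.positions_um[np.argmax(prof.per_channel_values["ddr1"])]
        mid = prof.positions_um[-1] / 2
        assert abs(peak_pos - mid) <= 2 * PX + 1e-9

    def test_zero_length_rejected(self):
        planes = {"a": ImagePlane(np.ones((32, 32)), PX)}
        with pytest.raises(ValueError, match="zero-length"):
            extract_profile(planes, (4, 4), (4, 4))

    def test_endpoint_outside_frame_rejected(self):
        planes = {"a": ImagePlane(np.ones((32, 32)), PX)}
        with pytest.raises(ValueError, match="outside"):
            extract_profile(planes, (4, 4), (40, 4))


class TestMinmaxNormalize:
    def test_three_point_example(self):
        prof = _profile([2.0, 4.0, 6.0])
        out = minmax_normalize(prof)
        assert out.per_channel_values["a"].tolist() == [0.0, 50.0, 100.0]

    def test_already_normalized_unchanged(self):
        prof = _profile([0.0, 25.0, 100.0])
        out = minmax_normalize(prof)
        assert out.per_channel_values["a"].tolist() == [0.0, 25.0, 100.0]

    def test_order_preserved(self, rng):
        vals = rng.normal(size=50)
        out = minmax_normalize(_profile(vals))
        assert np.array_equal(np.argsort(out.per_channel_values["a"]), np.argsort(vals))

    def test_constant_channel_rejected_by_name(self):
        with pytest.raises(ValueError, match="'a'"):
            minmax_normalize(_profile([3.0, 3.0, 3.0]))


def _profile(values):
    from zctexture.profiles import LineProfile

    values = np.asarray(values, float)
    return LineProfile(
        positions_um=np.arange(len(values), dtype=float) * PX,
        per_channel_values={"a": values},
        line_width_um=0.2,
        endpoints=((0.0, 0.0), (0.0, float(len(values) - 1))),
    )


class TestFWHM:
    def test_gaussian_analytic(self):
        x = np.arange(81) * 0.1
        sigma = 0.2  # um  (2 px at 0.1 um/px)
        v = np.exp(-((x - 4.0) ** 2) / (2 * sigma**2))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert abs(fwhm(v, x) / expected - 1) < 0.02

    def test_triangle_geometry(self):
        v = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        x = np.arange(len(v), dtype=float)
        assert fwhm(v, x) == pytest.approx(5.0)

    def test_taller_of_two_separated_gaussians(self):
        x = np.arange(200) * 0.1
        v = np.exp(-((x - 5.0) ** 2) / (2 * 0.2**2)) + 0.5 * np.exp(
            -((x - 15.0) ** 2) / (2 * 0.2**2)
        )
        expected = 2 * np.sqrt(2 * np.log(2)) * 0.2
        assert abs(fwhm(v, x) / expected - 1) < 0.02

    def test_affine_intensity_invariance(self):
        x = np.arange(81) * 0.1
        v = np.exp(-((x - 4.0) ** 2) / (2 * 0.2**2))
        assert fwhm(5.0 * v + 2.0, x) == pytest.approx(fwhm(v, x))

    def test_peak_at_edge_raises(self):
        x = np.arange(20, dtype=float)
        v = np.exp(-((x - 0.0) ** 2) / 8.0)
        with pytest.raises(ValueError, match="left"):
            fwhm(v, x)


class TestDoubleWall:
    def test_synthetic_pair_detected_with_gap(self):
        x = np.arange(41) * PX
        wall = 100 * (
            np.exp(-((x - 0.6) ** 2) / (2 * 0.05**2))
            + np.exp(-((x - 0.8) ** 2) / (2 * 0.05**2))
        )
        filler = 100 * np.exp(-((x - 0.7) ** 2) / (2 * 0.05**2))
        res = detect_double_wall(wall, filler, x)
        assert res.is_double_wall
        assert abs(res.gap_um - 0.2) <= 0.04

    def test_single_ridge_not_detected(self):
        x = np.arange(41) * PX
        wall = 100 * np.exp(-((x - 0.7) ** 2) / (2 * 0.08**2))
        res = detect_double_wall(wall, wall, x)
        assert not res.is_double_wall
        assert res.reason == "single_peak"

    def test_filler_outside_trough_rejected_with_reason(self):
        x = np.arange(41) * PX
        wall = 100 * (
            np.exp(-((x - 0.6) ** 2) / (2 * 0.05**2))
            + np.exp(-((x - 0.8) ** 2) / (2 * 0.05**2))
        )
        filler = 100 * np.exp(-((x - 1.3) ** 2) / (2 * 0.05**2))
        res = detect_double_wall(wall, filler, x)
        assert not res.is_double_wall
        assert res.reason == "filler_offset"

    def test_generator_double_wall_scene_detected(self):
        scene = dw_scene(3)
        p0, p1 = probe_line_for_scene(scene, length_um=1.0)
        prof = minmax_normalize(extract_profile(scene.channels, p0, p1, line_width_um=0.2))
        res = detect_double_wall(
            prof.per_channel_values["ddr1"], prof.per_channel_values["py"], prof.positions_um
        )
        assert res.is_double_wall
        assert abs(res.gap_um - 0.2) / 0.2 <= 0.2

    def test_sensitivity_and_fpr_on_labelled_scenes(self):
        """Classification quality on a small labelled cohort (the full 200-scene
        check runs in the acceptance suite)."""
        hits = 0
        for s in range(25):
            scene = dw_scene(s)
            p0, p1 = probe_line_for_scene(scene, length_um=1.0)
            prof = minmax_normalize(extract_profile(scene.channels, p0, p1, line_width_um=0.2))
            hits += detect_double_wall(
                prof.per_channel_values["ddr1"], prof.per_channel_values["py"], prof.positions_um
            ).is_double_wall
        false = 0
        for s in range(25):
            scene = ridge_scene(100 + s)
            p0, p1 = probe_line_for_scene(scene, length_um=1.0)
            prof = minmax_normalize(extract_profile(scene.channels, p0, p1, line_width_um=0.2))
            false += detect_double_wall(
                prof.per_channel_values["ddr1"], prof.per_channel_values["py"], prof.positions_um
            ).is_double_wall
        assert hits >= 22 and false <= 3


class TestProbeHelpers:
    def test_perpendicular_line_crosses_midpoint(self):
        centre = np.array([[30.0, 10.0], [30.0, 30.0]])
        p0, p1 = perpendicular_probe_line(centre, 1.0, PX, (64, 64))
        mid = 0.5 * (np.array(p0) + np.array(p1))
        np.testing.assert_allclose(mid, [30.0, 20.0], atol=1.0)
        # perpendicular to a horizontal segment means vertical
        assert abs(p0[1] - p1[1]) < 1e-6

    def test_probe_line_for_scene_deterministic(self):
        scene = dw_scene(7)
        assert probe_line_for_scene(scene) == probe_line_for_scene(scene)
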