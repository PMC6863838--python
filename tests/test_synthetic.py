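"""Tests of the synthetic scene generator and its ground truth."""

import numpy as np
import pytest

from zctexture.image import ImagePlane
from zctexture.synthetic import (
    SceneConfig,
    corrupt,
    generate_cell_shape,
    generate_scene,
    generate_timecourse,
    render_texture,
)


class TestCellShape:
    def test_deterministic_given_seed(self):
        a = generate_cell_shape((128, 128), seed=1)
        b = generate_cell_shape((128, 128), seed=1)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cell_shape((128, 128), seed=1)
        b = generate_cell_shape((128, 128), seed=2)
        assert not np.array_equal(a, b)

    def test_area_fraction_within_contract_over_seeds(self):
        fracs = [generate_cell_shape((128, 128), seed=s).mean() for s in range(100)]
        assert 0.2 <= min(fracs) and max(fracs) <= 0.6

    def test_simply_connected(self):
        from scipy import ndimage

        for s in range(10):
            m = generate_cell_shape((128, 128), seed=s)
            _, n = ndimage.label(m)
            assert n == 1
            _, nholes = ndimage.label(~m & ndimage.binary_fill_holes(m))
            assert nholes == 0

    def test_rejects_small_frames(self):
        with pytest.raises(ValueError, match="64"):
            generate_cell_shape((32, 128), seed=0)


class TestRenderTexture:
    def test_zero_density_punctate_is_flat_baseline(self):
        cfg = SceneConfig(density=0.0, baseline_frac=0.0)
        mask = generate_cell_shape(cfg.image_shape, 0)
        channels, centrelines = render_texture(cfg, mask, np.random.default_rng(0))
        assert channels["ddr1"].max() == 0.0
        assert centrelines == []

    def test_amplitude_scaling_is_exactly_linear(self):
        mask = generate_cell_shape((128, 128), 0)
        for cls in ("punctate", "linear_cidc", "aggregate", "double_wall"):
            cfg1 = SceneConfig(texture_class=cls, char_length_um=0.3, seed=4)
            cfg2 = cfg1.replace(amplitude=2 * cfg1.amplitude, py_amplitude=2 * cfg1.py_amplitude,
                                collagen_amplitude=2 * cfg1.collagen_amplitude)
            ch1, _ = render_texture(cfg1, mask, np.random.default_rng(7))
            ch2, _ = render_texture(cfg2, mask, np.random.default_rng(7))
            for name in ch1:
                np.testing.assert_allclose(ch2[name], 2.0 * ch1[name], rtol=0, atol=1e-9)

    def test_signal_zero_outside_mask(self):
        cfg = SceneConfig(seed=3)
        mask = generate_cell_shape(cfg.image_shape, 3)
        channels, _ = render_texture(cfg, mask, np.random.default_rng(3))
        assert channels["ddr1"][~mask].max() == 0.0

    def test_double_wall_trough_at_centreline(self):
        """The receptor channel dips at the centreline relative to +-g/2 offsets."""
        cfg = SceneConfig(
            texture_class="double_wall", char_length_um=0.2, pixel_size_um=0.04,
            density=0.2, seed=5, baseline_frac=0.0,
        )
        mask = generate_cell_shape(cfg.image_shape, 5)
        channels, centrelines = render_texture(cfg, mask, np.random.default_rng(5))
        g_px = cfg.char_length_um / cfg.pixel_size_um
        wall = channels["ddr1"]
        checked = 0
        for poly in centrelines:
            poly = np.asarray(poly, float)
            if len(poly) < 3:
                continue
            mid = len(poly) // 2
            tang = poly[mid + 1] - poly[mid - 1]
            tang /= np.linalg.norm(tang)
            normal = np.array([-tang[1], tang[0]])
            p = poly[mid]
            at = lambda q: wall[int(round(q[0])), int(round(q[1]))]
            centre = at(p)
            side = min(at(p + 0.5 * g_px * normal), at(p - 0.5 * g_px * normal))
            if side > 0:
                assert centre < side
                checked += 1
        assert checked >= 1

    def test_double_wall_filler_peaks_in_gap(self):
        cfg = SceneConfig(
            texture_class="double_wall", char_length_um=0.2, pixel_size_um=0.04,
            density=0.2, seed=5, baseline_frac=0.0,
        )
        mask = generate_cell_shape(cfg.image_shape, 5)
        channels, centrelines = render_texture(cfg, mask, np.random.default_rng(5))
        poly = np.asarray(max(centrelines, key=len), float)
        mid = poly[len(poly) // 2]
        r, c = int(round(mid[0])), int(round(mid[1]))
        assert channels["py"][r, c] > 0.3 * cfg.amplitude
        assert channels["collagen"][r, c] > 0.3 * cfg.amplitude

    def test_centrelines_inside_cell_mask(self):
        for cls in ("punctate", "linear_cidc", "aggregate"):
            cfg = SceneConfig(texture_class=cls, char_length_um=0.4, seed=9)
            scene = generate_scene(cfg)
            for poly in scene.truth.structure_centrelines:
                for p in np.asarray(poly, float):
                    r, c = int(round(p[0])), int(round(p[1]))
                    assert scene.truth.cell_mask[r, c]

    def test_empty_mask_rejected(self):
        cfg = SceneConfig()
        with pytest.raises(ValueError, match="empty"):
            render_texture(cfg, np.zeros((128, 128), bool))


class TestCorrupt:
    def test_identity_when_all_confounds_off(self):
        cfg = SceneConfig(
            illumination_amplitude=0.0, noise_poisson=False, noise_gaussian_sd=0.0, ruffle_count=0
        )
        mask = generate_cell_shape(cfg.image_shape, 0)
        channels, _ = render_texture(cfg, mask, np.random.default_rng(0))
        plane, illum, ruffle = corrupt(channels["ddr1"], cfg, np.random.default_rng(1), mask)
        np.testing.assert_array_equal(plane.data, channels["ddr1"])
        assert illum.min() == illum.max() == 1.0
        assert not ruffle.any()

    def test_reproducible_given_seed(self):
        cfg = SceneConfig(ruffle_count=2)
        mask = generate_cell_shape(cfg.image_shape, 0)
        channels, _ = render_texture(cfg, mask, np.random.default_rng(0))
        a, _, _ = corrupt(channels["ddr1"], cfg, np.random.default_rng(9), mask)
        b, _, _ = corrupt(channels["ddr1"], cfg, np.random.default_rng(9), mask)
        np.testing.assert_array_equal(a.data, b.data)

    def test_gaussian_noise_moment(self):
        """Additive noise on a blank frame recovers the configured sd within 5%."""
        cfg = SceneConfig(
            illumination_amplitude=0.0, noise_poisson=False, noise_gaussian_sd=3.0, ruffle_count=0
        )
        plane, _, _ = corrupt(np.zeros((128, 128)), cfg, np.random.default_rng(2))
        assert abs(plane.data.std() / 3.0 - 1.0) < 0.05

    def test_negative_input_rejected(self):
        cfg = SceneConfig()
        with pytest.raises(ValueError, match="non-negative"):
            corrupt(np.full((8, 8), -1.0), cfg, np.random.default_rng(0))

    def test_ruffles_near_mask_boundary(self):
        from scipy import ndimage

        cfg = SceneConfig(ruffle_count=3, seed=8)
        scene = generate_scene(cfg)
        rm = scene.truth.ruffle_mask
        if rm.any():
            boundary = scene.truth.cell_mask ^ ndimage.binary_erosion(scene.truth.cell_mask)
            # ruffle centres sit within ~1 um of the boundary; allow the blob extent
            halo = ndimage.binary_dilation(boundary, iterations=int(2.5 / cfg.pixel_size_um))
            assert (rm & ~halo).sum() == 0


class TestSceneAssembly:
    def test_scene_determinism_bitwise(self):
        cfg = SceneConfig(seed=21, ruffle_count=1)
        s1, s2 = generate_scene(cfg), generate_scene(cfg)
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name].data, s2.channels[name].data)
        np.testing.assert_array_equal(s1.truth.cell_mask, s2.truth.cell_mask)

    def test_channels_share_shape_and_pixel_size(self, default_scene):
        shapes = {p.data.shape for p in default_scene.channels.values()}
        sizes = {p.pixel_size_um for p in default_scene.channels.values()}
        assert len(shapes) == 1 and len(sizes) == 1

    def test_noiseless_truth_nonnegative(self, default_scene):
        for grid in default_scene.truth.per_channel_truth.values():
            assert grid.min() >= 0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="texture_class"):
            SceneConfig(texture_class="nope")
        with pytest.raises(ValueError, match="resolvable"):
            SceneConfig(char_length_um=0.1, pixel_size_um=0.1)
        with pytest.raises(ValueError, match="amplitude"):
            SceneConfig(amplitude=0.0)


class TestTimecourse:
    def test_single_time_gives_single_punctate_scene(self):
        scenes = generate_timecourse([0.0], seed=1)
        assert len(scenes) == 1
        assert scenes[0].config.texture_class == "punctate"

    def test_char_length_strictly_increases(self):
        scenes = generate_timecourse([0.0, 10.0, 60.0], seed=1)
        lengths = [s.config.char_length_um for s in scenes]
        assert lengths[0] < lengths[1] < lengths[2]
        assert [s.config.texture_class for s in scenes] == [
            "punctate", "linear_cidc", "aggregate"
        ]

    def test_reproducible(self):
        a = generate_timecourse([0.0, 60.0], seed=4)
        b = generate_timecourse([0.0, 60.0], seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.channels["ddr1"].data, sb.channels["ddr1"].data)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            generate_timecourse([], seed=0)
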