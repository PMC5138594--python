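"""Band-pass textures, posterisation, boundary distances, edge enhancement,
and target compositing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from camoedge.background import SceneCanvas
from camoedge.colors import LabColor
from camoedge.texture import (
    DegenerateTextureError,
    EdgeProfile,
    FilterSpec,
    PatchMap,
    PlacementError,
    apply_edge_enhancement,
    bandpass_noise,
    boundary_distance,
    clear_central_band,
    compose_stimulus,
    median_patch_breadth,
    posterise,
    snake_mask,
)

DARK = LabColor(40.0, 10.0, 20.0)
LIGHT = LabColor(55.0, 12.0, 25.0)


class TestBandpassNoise:
    def test_output_shape_and_zero_mean(self, rng):
        t = bandpass_noise((64, 96), FilterSpec(), rng)
        assert t.shape == (64, 96)
        assert abs(t.mean()) < 1e-12

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpass_noise((32, 128), FilterSpec(), rng)

    def test_filter_is_band_pass_not_low_pass(self):
        # DC gain must be no more than 10% of the pass-band peak gain
        filt = FilterSpec()
        d = np.linspace(0, 0.5, 2001)
        profile = filt.radial_amplitude(d)
        assert profile[0] <= 0.10 * profile.max()

    def test_posterised_patch_scale_matches_leaf_scale(self):
        # median patch breadth (same-label run length) sits at the 21-px
        # modal leaf length the texture is calibrated to
        breadths = []
        for seed in range(20):
            t = bandpass_noise((256, 256), FilterSpec(), np.random.default_rng(seed))
            pm, _ = posterise(t, DARK, LIGHT)
            breadths.append(median_patch_breadth(pm.labels))
        assert np.median(breadths) == pytest.approx(21.0, abs=6.0)


class TestPosterise:
    def test_median_split_is_exactly_half_on_even_grids(self, rng):
        t = bandpass_noise((128, 128), FilterSpec(), rng)
        pm, lab = posterise(t, DARK, LIGHT)
        assert (pm.labels == 0).mean() == 0.5
        assert (pm.labels == 1).mean() == 0.5

    def test_constant_texture_is_degenerate(self):
        with pytest.raises(DegenerateTextureError):
            posterise(np.ones((64, 64)), DARK, LIGHT)

    def test_swapping_colours_relabels_without_moving_the_boundary(self, rng):
        t = bandpass_noise((64, 64), FilterSpec(), rng)
        _, lab_a = posterise(t, DARK, LIGHT)
        _, lab_b = posterise(t, LIGHT, DARK)
        # same boundary: where a shows DARK, b shows LIGHT and vice versa
        a_dark = np.all(lab_a == DARK.as_array(), axis=-1)
        b_light = np.all(lab_b == LIGHT.as_array(), axis=-1)
        np.testing.assert_array_equal(a_dark, b_light)


def brute_force_boundary_distance(labels: np.ndarray) -> np.ndarray:
    """All-pairs oracle: min centre distance to any opposite pixel, minus 1."""
    h, w = labels.shape
    coords = np.argwhere(np.ones_like(labels, dtype=bool))
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            opp = coords[labels[coords[:, 0], coords[:, 1]] != labels[r, c]]
            d = np.hypot(opp[:, 0] - r, opp[:, 1] - c)
            out[r, c] = d.min() - 1.0
    return out


class TestBoundaryDistance:
    def test_checkerboard_distances_all_equal(self):
        labels = np.indices((2, 2)).sum(axis=0) % 2
        d = boundary_distance(labels)
        assert np.all(d == d[0, 0])

    def test_half_split_increments_one_px_per_column(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        d = boundary_distance(labels)
        np.testing.assert_allclose(d[0], [4, 3, 2, 1, 0, 0, 1, 2, 3, 4])

    def test_invariant_to_label_inversion(self, rng):
        labels = (rng.random((12, 12)) > 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0, 0] = 1 - labels[0, 0]
        np.testing.assert_array_equal(
            boundary_distance(labels), boundary_distance(1 - labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            boundary_distance(np.zeros((4, 4), dtype=int))

    @given(
        hnp.arrays(
            np.int8,
            st.tuples(st.integers(2, 16), st.integers(2, 16)),
            elements=st.integers(0, 1),
        )
    )
    def test_matches_all_pairs_oracle_on_small_images(self, labels):
        labels = labels.astype(int)
        if labels.min() == labels.max():
            return
        np.testing.assert_allclose(
            boundary_distance(labels), brute_force_boundary_distance(labels),
            atol=1e-9,
        )


def half_split_patchmap(n: int = 40) -> PatchMap:
    labels = np.zeros((n, n), dtype=int)
    labels[:, n // 2 :] = 1
    return PatchMap.from_labels(labels)


class TestEdgeEnhancement:
    def test_none_variant_is_the_posterised_image(self, rng):
        t = bandpass_noise((64, 64), FilterSpec(), rng)
        pm, lab = posterise(t, DARK, LIGHT)
        out, clipped = apply_edge_enhancement(pm, DARK, LIGHT, EdgeProfile("none"))
        np.testing.assert_array_equal(out, lab)
        assert not clipped

    def test_both_variant_ramp_endpoints_and_monotonicity(self):
        # offset 40 on light.L = 55: boundary pixels reach L = 95, pixels at
        # or beyond the 16-px width stay at 55, monotone in between
        pm = half_split_patchmap(80)
        prof = EdgeProfile("both", offset=40, width=16)
        out, _ = apply_edge_enhancement(pm, DARK, LIGHT, prof)
        L = out[..., 0]
        light = pm.labels.astype(bool)
        assert np.all(L[light & (pm.dist == 0)] == 95.0)
        assert np.all(L[light & (pm.dist >= 16)] == 55.0)
        row_L = L[0, 40:]  # light side, dist increasing away from boundary
        assert np.all(np.diff(row_L) <= 1e-12)
        dark = ~light
        assert np.all(L[dark & (pm.dist == 0)] == 0.0)  # 40 - 40
        assert np.all(L[dark & (pm.dist >= 16)] == 40.0)

    @pytest.mark.parametrize("variant", ["both", "no_low", "no_high"])
    def test_ramp_is_continuous_and_equals_patch_value_at_width(self, variant):
        pm = half_split_patchmap(64)
        prof = EdgeProfile(variant, offset=20, width=8)
        out, _ = apply_edge_enhancement(pm, DARK, LIGHT, prof)
        L = out[..., 0]
        at_width = pm.dist == 8
        patch_L = np.where(pm.labels.astype(bool), LIGHT.L, DARK.L)
        assert np.all(L[at_width] == patch_L[at_width])

    def test_no_high_keeps_light_patches_untouched(self):
        pm = half_split_patchmap(64)
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile("no_high", offset=40, width=16)
        )
        light = pm.labels.astype(bool)
        assert np.all(out[..., 0][light] == LIGHT.L)
        dark_boundary = (~light) & (pm.dist == 0)
        assert np.all(out[..., 0][dark_boundary] == 0.0)

    def test_no_low_keeps_dark_patches_untouched(self):
        pm = half_split_patchmap(64)
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile("no_low", offset=20, width=16)
        )
        dark = ~pm.labels.astype(bool)
        assert np.all(out[..., 0][dark] == DARK.L)

    def test_square_variant_has_flat_bands_and_no_gradient(self):
        pm = half_split_patchmap(64)
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile("square", offset=20, width=8)
        )
        L = out[..., 0]
        light = pm.labels.astype(bool)
        in_band = pm.dist < 8
        assert np.all(L[light & in_band] == LIGHT.L + 20)
        assert np.all(L[light & ~in_band] == LIGHT.L)
        assert np.all(L[~light & in_band] == DARK.L - 20)
        assert np.all(L[~light & ~in_band] == DARK.L)

    @pytest.mark.parametrize("variant", ["none", "both", "no_low", "no_high", "square"])
    def test_zero_offset_is_identity_for_every_variant(self, variant, rng):
        t = bandpass_noise((64, 64), FilterSpec(), rng)
        pm, lab = posterise(t, DARK, LIGHT)
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile(variant, offset=0, width=8)
        )
        np.testing.assert_array_equal(out, lab)

    @pytest.mark.parametrize("variant", ["both", "no_low", "no_high", "square"])
    def test_lightness_never_exceeds_patch_plus_offset(self, variant, rng):
        t = bandpass_noise((64, 64), FilterSpec(), rng)
        pm, _ = posterise(t, DARK, LIGHT)
        offset = 30
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile(variant, offset=offset, width=4)
        )
        L = out[..., 0]
        light = pm.labels.astype(bool)
        assert L[light].max() <= LIGHT.L + offset + 1e-12
        assert L[light].min() >= LIGHT.L - 1e-12
        assert L[~light].min() >= DARK.L - offset - 1e-12
        assert L[~light].max() <= DARK.L + 1e-12

    def test_out_of_range_lightness_is_clipped_and_flagged(self):
        pm = half_split_patchmap(32)
        out, clipped = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile("both", offset=60, width=8)
        )
        assert clipped
        assert out[..., 0].max() <= 100.0 and out[..., 0].min() >= 0.0

    def test_chromatic_channels_untouched(self):
        pm = half_split_patchmap(32)
        out, _ = apply_edge_enhancement(
            pm, DARK, LIGHT, EdgeProfile("both", offset=40, width=8)
        )
        light = pm.labels.astype(bool)
        assert np.all(out[..., 1][light] == LIGHT.A)
        assert np.all(out[..., 2][~light] == DARK.B)


class TestSnakeTarget:
    def test_major_axis_extent(self):
        m = snake_mask(350, 0.0)
        assert abs(m.mask.shape[1] - 350) <= 1

    def test_vertical_orientation_swaps_axes(self):
        m = snake_mask(200, np.pi / 2)
        h, w = m.mask.shape
        assert abs(h - 200) <= 1
        assert w < h

    def test_single_connected_component(self):
        from scipy import ndimage

        m = snake_mask(150, 0.7)
        _, n = ndimage.label(m.mask)
        assert n == 1

    def test_make_target_seed_determinism(self, forest_pop):
        from camoedge.colors import PatchColorRule
        from camoedge.texture import make_target

        args = (forest_pop, PatchColorRule(), FilterSpec(),
                EdgeProfile("both", 20, 8), 120.0, 0.4)
        m1, lab1 = make_target(*args, np.random.default_rng(11))
        m2, lab2 = make_target(*args, np.random.default_rng(11))
        np.testing.assert_array_equal(m1.mask, m2.mask)
        np.testing.assert_array_equal(lab1, lab2)


class TestComposeStimulus:
    def _target(self, forest_pop, length=60):
        from camoedge.colors import PatchColorRule
        from camoedge.texture import make_target

        return make_target(
            forest_pop, PatchColorRule(), FilterSpec(), EdgeProfile("none"),
            length, 0.0, np.random.default_rng(21),
        )

    def test_differs_from_background_exactly_on_mask(self, forest_pop):
        bg = SceneCanvas.uniform(600, 300, 0.42)
        target = self._target(forest_pop)
        stim = compose_stimulus(bg, target, 3, np.random.default_rng(1))
        diff = np.any(stim.canvas.pixels != bg.pixels, axis=-1)
        t, l, b, r = stim.target_bbox
        placed = np.zeros_like(diff)
        placed[t:b, l:r] = target[0].mask
        changed_only_under_mask = diff & ~placed
        assert not changed_only_under_mask.any()

    def test_bbox_always_inside_requested_cell(self, forest_pop):
        bg = SceneCanvas.uniform(600, 300, 0.42)
        target = self._target(forest_pop)
        for seed in range(300):
            cell = seed % 8 + 1
            stim = compose_stimulus(bg, target, cell, np.random.default_rng(seed))
            t, l, b, r = stim.target_bbox
            row, col = divmod(cell - 1, 4)
            assert row * 150 <= t and b <= (row + 1) * 150
            assert col * 150 <= l and r <= (col + 1) * 150

    def test_central_band_is_leaf_free_in_depth_layout(self, forest_pop):
        from camoedge.background import render_background

        base = SceneCanvas.uniform(500, 500, 0.5)
        scene = render_background(base, 400, forest_pop, np.random.default_rng(2))
        cleared = clear_central_band(scene, base, (4.49, 13.80))
        bw = round(4.49 / base.deg_per_px)
        bh = round(13.80 / base.deg_per_px)
        top, left = (500 - bh) // 2, (500 - bw) // 2
        band = cleared.pixels[top : top + bh, left : left + bw]
        assert np.all(band == 0.5)

    def test_oversized_target_raises_placement_error(self, forest_pop):
        bg = SceneCanvas.uniform(200, 100, 0.5)
        target = self._target(forest_pop, length=90)
        with pytest.raises(PlacementError):
            compose_stimulus(bg, target, 1, np.random.default_rng(0))
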