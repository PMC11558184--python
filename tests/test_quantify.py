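"""Quantification pipeline: segmentation, subtraction, crops, profiles, maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberclot import (
    ChamberSpec,
    VoxelVolume,
    clot_at_equivalent_distance,
    crop_volume,
    dice_coefficient,
    normalize_clot_volume,
    probability_map,
    project_axis,
    render_grayscale,
    segment_volume,
    slice_profile,
    subtract_mask,
)


@pytest.fixture(scope="module")
def uniform_clot(small_solid, small_spec):
    """Every fluid voxel clotted: clot = NOT solid (walls included as solid)."""
    from fiberclot.volume import ClotSegmentation

    clot = small_solid.with_grid(~small_solid.grid)
    return ClotSegmentation(clot=clot, spec=small_spec)


class TestSegmentation:
    def test_noiseless_phantom_segmented_exactly(self, render_solid, render_clot):
        gray = render_grayscale(render_solid, render_clot.clot, psf_sigma=0.0, noise_sd=0.0)
        mask = segment_volume(gray)
        truth = render_solid.grid | render_clot.clot.grid
        assert np.array_equal(mask.grid, truth)

    def test_fixed_threshold_matches_otsu_on_noiseless(self, render_solid, render_clot):
        gray = render_grayscale(render_solid, render_clot.clot, psf_sigma=0.0, noise_sd=0.0)
        assert np.array_equal(
            segment_volume(gray, method="fixed", threshold=0.4).grid,
            segment_volume(gray, method="otsu_two_stage").grid,
        )

    def test_default_noise_dice(self, render_solid, render_clot):
        gray = render_grayscale(render_solid, render_clot.clot, seed=5)
        mask = segment_volume(gray)
        truth = VoxelVolume(render_solid.grid | render_clot.clot.grid, gray.voxel_size)
        assert dice_coefficient(mask, truth) >= 0.95

    def test_flat_image_rejected(self):
        flat = VoxelVolume(np.full((4, 4, 4), 0.5), 20.0)
        with pytest.raises(ValueError, match="flat"):
            segment_volume(flat)


class TestSubtraction:
    def test_clean_minus_clean_is_empty(self, small_solid):
        assert subtract_mask(small_solid, small_solid).grid.sum() == 0

    def test_known_added_voxels_recovered_exactly(self, small_solid):
        seg = small_solid.with_grid(small_solid.grid.copy())
        fluid = np.flatnonzero(~small_solid.grid.ravel())[:137]
        seg.grid.ravel()[fluid] = True
        clot = subtract_mask(seg, small_solid)
        assert clot.grid.sum() == 137
        assert not np.any(clot.grid & small_solid.grid)

    def test_simulated_clot_recovered_in_noiseless_mode(self, render_solid, render_clot):
        gray = render_grayscale(render_solid, render_clot.clot, psf_sigma=0.0, noise_sd=0.0)
        clot = subtract_mask(segment_volume(gray), render_solid)
        assert np.array_equal(clot.grid, render_clot.clot.grid)

    def test_shape_mismatch_rejected(self, small_solid):
        other = VoxelVolume(np.zeros((3, 3, 3), bool), small_solid.voxel_size)
        with pytest.raises(ValueError, match="shapes differ"):
            subtract_mask(other, small_solid)


class TestCrop:
    def test_default_margins_on_study_chamber(self):
        vol = VoxelVolume(np.zeros((365, 150, 1000), bool), 20.0)  # 7.3 x 3 x 20 mm
        out = crop_volume(vol)
        vs = vol.voxel_size_mm
        assert abs(out.extent_mm[0] - 4.7) <= vs
        assert abs(out.extent_mm[1] - 2.2) <= vs
        assert abs(out.extent_mm[2] - 19.0) <= vs
        assert out.origin == (1.3, 0.4, 1.0)

    def test_zero_margins_identity_and_idempotent(self, small_solid):
        once = crop_volume(small_solid, 0.0, 0.0, 0.0)
        twice = crop_volume(once, 0.0, 0.0, 0.0)
        assert np.array_equal(once.grid, small_solid.grid)
        assert np.array_equal(twice.grid, small_solid.grid)

    def test_outlet_edge_untouched(self, small_solid):
        out = crop_volume(small_solid)
        mx = int(np.ceil(1.3 / small_solid.voxel_size_mm))
        my = int(np.ceil(0.4 / small_solid.voxel_size_mm))
        assert np.array_equal(out.grid[..., -1], small_solid.grid[mx:-mx, my:-my, -1])

    def test_excessive_margins_rejected(self, small_solid):
        with pytest.raises(ValueError, match="margins"):
            crop_volume(small_solid, sides=4.0)

    @given(m=st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=20, deadline=None)
    def test_margin_snapping_never_under_crops(self, m):
        vol = VoxelVolume(np.zeros((50, 50, 50), bool), 40.0)
        out = crop_volume(vol, top_bottom=m, sides=m, inlet=m)
        assert out.extent_mm[0] <= vol.extent_mm[0] - 2 * m + 1e-9
        assert out.extent_mm[2] <= vol.extent_mm[2] - m + 1e-9


class TestSliceProfile:
    def test_empty_clot_all_zero(self, small_solid, small_spec):
        empty = small_solid.with_grid(np.zeros_like(small_solid.grid))
        prof = slice_profile(empty, spec=small_spec, mode="five_segments")
        assert np.all(prof.clot_volume == 0)
        assert np.all(prof.normalized_fraction == 0)

    def test_tiling_partitions_total_volume(self, small_clot):
        cropped = crop_volume(small_clot.clot)
        prof = slice_profile(cropped, spec=small_clot.spec, mode="tiling")
        assert prof.total_volume() == pytest.approx(cropped.binary_volume_mm3(), abs=1e-12)

    def test_five_segments_each_below_total(self, small_clot):
        cropped = crop_volume(small_clot.clot)
        prof = slice_profile(cropped, spec=small_clot.spec, mode="five_segments")
        assert len(prof.clot_volume) == 5
        assert np.all(prof.clot_volume <= cropped.binary_volume_mm3() + 1e-12)
        assert np.all((prof.normalized_fraction >= 0) & (prof.normalized_fraction <= 1))

    def test_uniform_clot_tiling_matches_void_fraction(self, uniform_clot):
        """Fully clotted void, cropped away from walls: each tiled segment
        holds ~ segment length x cropped W x cropped H x (1 - PD)."""
        cropped = crop_volume(uniform_clot.clot)
        prof = slice_profile(cropped, spec=uniform_clot.spec, mode="tiling")
        expected = (
            prof.segment_length
            * cropped.extent_mm[0]
            * cropped.extent_mm[1]
            * (1 - uniform_clot.spec.packing_density)
        )
        full = prof.clot_volume[:-1] if len(prof.clot_volume) > 1 else prof.clot_volume
        assert np.all(np.abs(full - expected) / expected < 0.06)

    def test_oversized_segment_rejected(self, small_clot):
        with pytest.raises(ValueError, match="exceeds"):
            slice_profile(small_clot.clot, spec=small_clot.spec, segment_length=99.0)


class TestNormalization:
    def test_reference_value(self):
        spec = ChamberSpec(packing_density=0.5)
        assert normalize_clot_volume(21.9, spec, 438.0) == pytest.approx(0.10)

    def test_zero_and_full_occlusion(self):
        spec = ChamberSpec(packing_density=0.5)
        assert normalize_clot_volume(0.0, spec, 438.0) == 0.0
        assert normalize_clot_volume(219.0, spec, 438.0) == pytest.approx(1.0)

    def test_impossible_volume_rejected(self):
        spec = ChamberSpec(packing_density=0.5)
        with pytest.raises(ValueError, match="impossible"):
            normalize_clot_volume(300.0, spec, 438.0)

    @given(v=st.floats(min_value=0.0, max_value=100.0), scale=st.floats(min_value=0.1, max_value=2.0))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_clot_volume(self, v, scale):
        spec = ChamberSpec(packing_density=0.5)
        base = normalize_clot_volume(v, spec, 438.0)
        assert normalize_clot_volume(v * scale, spec, 438.0) == pytest.approx(base * scale, rel=1e-9)


class TestProbabilityMap:
    def test_single_replicate_is_its_own_map(self, small_clot):
        pmap = probability_map([small_clot])
        assert np.array_equal(pmap.probabilities.grid, small_clot.clot.grid.astype(float))

    def test_half_occupancy_voxel(self):
        grids = [np.zeros((2, 2, 2), bool) for _ in range(6)]
        for g in grids[:3]:
            g[0, 0, 0] = True
        vols = [VoxelVolume(g, 40.0) for g in grids]
        pmap = probability_map(vols)
        assert pmap.probabilities.grid[0, 0, 0] == pytest.approx(0.5)

    def test_map_mean_equals_mean_clot_fraction(self, small_solid, small_spec, small_condition):
        from fiberclot import ClotSimParams, simulate_clot

        reps = [
            simulate_clot(small_solid, small_spec, small_condition, ClotSimParams(steps=5, seed=s))
            for s in range(3)
        ]
        pmap = probability_map(reps)
        mean_frac = np.mean([r.clot.grid.mean() for r in reps])
        assert pmap.probabilities.grid.mean() == pytest.approx(mean_frac, rel=1e-12)
        assert pmap.probabilities.grid.min() >= 0 and pmap.probabilities.grid.max() <= 1

    def test_replicate_order_invariance(self, small_solid, small_spec, small_condition):
        from fiberclot import ClotSimParams, simulate_clot

        reps = [
            simulate_clot(small_solid, small_spec, small_condition, ClotSimParams(steps=4, seed=s))
            for s in range(3)
        ]
        a = probability_map(reps).probabilities.grid
        b = probability_map(reps[::-1]).probabilities.grid
        assert np.array_equal(a, b)

    def test_grid_mismatch_rejected(self, small_solid):
        other = VoxelVolume(np.zeros((3, 3, 3), bool), small_solid.voxel_size)
        with pytest.raises(ValueError, match="do not match"):
            probability_map([small_solid, other])


class TestProjection:
    def test_uniform_map_projects_uniformly(self):
        vol = VoxelVolume(np.full((4, 5, 6), 0.3), 40.0)
        img = project_axis(vol, axis="rod_axis")
        assert img.shape == (4, 6)
        assert np.allclose(img, 0.3)

    def test_single_voxel_dilutes_by_slice_count(self):
        g = np.zeros((4, 5, 6), bool)
        g[1, 2, 3] = True
        img = project_axis(VoxelVolume(g, 40.0), axis="rod_axis")
        assert img[1, 3] == pytest.approx(1 / 5)

    def test_projection_preserves_mean(self, small_clot):
        pmap = probability_map([small_clot])
        img = project_axis(pmap, axis="rod_axis")
        assert img.mean() == pytest.approx(pmap.probabilities.grid.mean(), rel=1e-12)


class TestEquivalentDistanceSlab:
    def test_empty_clot_zero(self, small_solid, small_spec):
        empty = small_solid.with_grid(np.zeros_like(small_solid.grid))
        assert clot_at_equivalent_distance(empty, 3.0, path_length=small_spec.path_length) == 0.0

    def test_uniform_clot_slab_volume(self, uniform_clot):
        """Cropped, fully clotted void: 1 mm slab holds ~ 4.7 x 2.2 x (1 - PD) mm^3."""
        cropped = crop_volume(uniform_clot.clot, sides=1.3, top_bottom=0.4, inlet=1.0)
        got = clot_at_equivalent_distance(cropped, 5.0, slab=1.0, path_length=10.0)
        # cropped section is 4.7 x 0.7 mm for the flattened test chamber
        expect = 1.0 * cropped.extent_mm[0] * cropped.extent_mm[1] * 0.5
        assert got == pytest.approx(expect, rel=0.06)

    def test_slabs_partition_tiling_totals(self, small_clot):
        cropped = crop_volume(small_clot.clot)
        total = cropped.binary_volume_mm3()
        z0 = cropped.origin[2]
        zmax = z0 + cropped.extent_mm[2]
        slabs, d = [], z0
        while d < zmax - 1e-9:
            s = min(1.0, zmax - d)
            slabs.append(clot_at_equivalent_distance(cropped, d, slab=s, path_length=10.0))
            d += s
        assert sum(slabs) == pytest.approx(total, abs=1e-9)

    def test_out_of_range_rejected(self, small_clot):
        with pytest.raises(ValueError, match="outside"):
            clot_at_equivalent_distance(small_clot, 9.8, slab=1.0)
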