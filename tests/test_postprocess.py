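import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octseg.phantom import classmap_from_surfaces, generate_surfaces, generate_volume, volume_surfaces
from octseg.postprocess import (
    HoleFillConfig,
    adaptive_threshold,
    enforce_ordering,
    extract_surfaces,
    fill_holes,
    interpolate_missing,
    postprocess_maps,
    remove_outliers,
    smooth_surfaces,
    surfaces_from_maps,
)
from octseg.types import SurfaceSet


def _mask(n_n, n_z):
    m = np.zeros(n_n + n_z, dtype=bool)
    m[:n_n] = True
    return m.reshape(1, -1)


class TestAdaptiveThreshold:
    def test_direct_rule(self):
        assert adaptive_threshold(_mask(1000, 9000), 2) == 500.0

    def test_iterated_rule(self):
        # 9000/f < 1000 first holds at f=10 -> T=900
        assert adaptive_threshold(_mask(9000, 1000), 2) == 900.0

    def test_all_zero(self):
        assert adaptive_threshold(np.zeros((4, 4)), 2) == 0.0

    def test_all_ones_degenerates_to_zero(self):
        assert adaptive_threshold(np.ones((10, 10)), 2) == 0.0


class TestFillHoles:
    def test_single_pixel_hole_filled(self):
        cm = np.ones((40, 40), dtype=np.uint8)
        cm[10:30] = 2
        cm[35:] = 3
        cm[20, 20] = 1  # 1-px hole inside the class-2 band
        out = fill_holes(cm, HoleFillConfig())
        assert out[20, 20] == 2

    def test_small_island_removed(self):
        cm = np.ones((40, 40), dtype=np.uint8)
        cm[20:30] = 2
        cm[35:] = 3
        cm[5, 5:7] = 5  # 2-px island of class 5 in the vitreous
        out = fill_holes(cm, HoleFillConfig())
        assert (out[5, 5:7] == 1).all()

    def test_clean_map_is_fixed_point(self, small_params):
        s = generate_surfaces(small_params, 2)
        cm = classmap_from_surfaces(s, small_params.image_height)
        assert np.array_equal(fill_holes(cm), cm)

    def test_large_components_untouched(self, small_params):
        s = generate_surfaces(small_params, 1)
        cm = classmap_from_surfaces(s, small_params.image_height)
        corrupted = cm.copy()
        corrupted[3, 3] = 5
        out = fill_holes(corrupted)
        # the big bands keep their class everywhere except the repaired pixel
        assert np.array_equal(out, cm) or (out != cm).sum() <= 2


class TestExtractSurfaces:
    def test_inverse_of_construction(self, small_params):
        p = dataclasses.replace(small_params, thickness_jitter_sd=0.0)
        s = generate_surfaces(p, 0)
        integer_surfaces = SurfaceSet(np.ceil(s.values), s.axial_scale)
        cm = classmap_from_surfaces(integer_surfaces, p.image_height)
        extracted = extract_surfaces(cm)
        assert np.array_equal(extracted, integer_surfaces.values[:, 0, :])

    def test_fully_vitreous_column_all_missing(self):
        cm = np.ones((20, 5), dtype=np.uint8)
        cm[10:, 1:] = 9
        extracted = extract_surfaces(cm)
        assert np.isnan(extracted[:, 0]).all()
        assert extracted[7, 1] == 10  # BM = top of region 9

    def test_absent_region_leaves_specific_boundary_missing(self):
        # column contains regions 1..4 then jumps to 6: b4 (top of region 5) missing
        col = np.concatenate([np.full(5, 1), np.full(5, 2), np.full(5, 3),
                              np.full(5, 4), np.full(10, 6), np.full(10, 9)])
        cm = np.tile(col[:, None], (1, 3)).astype(np.uint8)
        extracted = extract_surfaces(cm)
        assert np.isnan(extracted[3, 0])  # INL-OPL boundary (top of region 5)
        assert extracted[4, 0] == 20  # OPL-ONL present (top of region 6)


class TestRemoveOutliers:
    def _flat(self, nb=5, na=30, gap=10.0):
        vals = np.arange(8)[:, None, None] * gap + 20.0
        return SurfaceSet(np.broadcast_to(vals, (8, nb, na)).copy(), axial_scale=2.0)

    def test_smooth_surfaces_unflagged(self):
        out = remove_outliers(self._flat(), tau_um=20.0)
        assert out.is_complete()

    def test_single_spike_flagged_with_neighbors(self):
        s = self._flat()
        s.values[3, 2, 15] += 25.0  # +50 um spike on one surface (axial 2 um/px)
        out = remove_outliers(s, tau_um=20.0)
        assert np.isnan(out.values[3, 2, 15])
        # both bounding surfaces of the affected layers go missing
        assert np.isnan(out.values[2, 2, 15]) or np.isnan(out.values[4, 2, 15])
        # stencil neighbors where the Laplacian exceeds tau are flagged too
        assert np.isnan(out.values[3, 2, 14]) and np.isnan(out.values[3, 2, 16])

    def test_negative_thickness_always_flagged(self):
        s = self._flat()
        s.values[4, 1, 7] = s.values[3, 1, 7] - 1.0  # crossing
        out = remove_outliers(s, tau_um=1e9)
        assert np.isnan(out.values[4, 1, 7]) and np.isnan(out.values[3, 1, 7])


class TestInterpolateMissing:
    def test_knots_preserved(self):
        vals = np.tile(np.linspace(10, 20, 16), (8, 3, 1))
        vals[2, 1, 5:8] = np.nan
        surf = SurfaceSet(vals.copy(), 1.0)
        out = interpolate_missing(surf)
        keep = np.isfinite(vals)
        assert np.allclose(out.values[keep], vals[keep])

    def test_linear_span_filled_exactly(self):
        row = np.linspace(0, 30, 16)
        vals = np.tile(row, (8, 1, 1))
        vals[0, 0, 4:9] = np.nan
        out = interpolate_missing(SurfaceSet(vals, 1.0))
        assert np.allclose(out.values[0, 0], row, atol=1e-9)

    def test_monotone_preserved(self):
        x = np.arange(20, dtype=float)
        knots = np.where(x % 3 == 0, np.nan, np.sqrt(x) * 5 + 10)
        vals = np.tile(knots, (8, 1, 1))
        out = interpolate_missing(SurfaceSet(vals, 1.0))
        assert (np.diff(out.values[0, 0]) >= -1e-9).all()  # PCHIP: no overshoot

    def test_edge_extrapolation_constant(self):
        vals = np.full((8, 1, 10), np.nan)
        vals[:, 0, 3] = 5.0
        vals[:, 0, 6] = 8.0
        out = interpolate_missing(SurfaceSet(vals, 1.0))
        assert (out.values[:, 0, :3] == 5.0).all()
        assert (out.values[:, 0, 7:] == 8.0).all()

    def test_row_without_knots_copies_nearest_bscan(self):
        vals = np.full((8, 3, 10), 7.0)
        vals[:, 2, :] = np.nan
        out = interpolate_missing(SurfaceSet(vals, 1.0))
        assert (out.values[:, 2, :] == 7.0).all()

    def test_no_knots_anywhere_raises(self):
        with pytest.raises(ValueError):
            interpolate_missing(SurfaceSet(np.full((8, 2, 10), np.nan), 1.0))


class TestSmoothSurfaces:
    def test_constant_unchanged(self):
        vals = np.full((8, 5, 9), 13.5)
        out = smooth_surfaces(SurfaceSet(vals, 1.0))
        assert np.allclose(out.values, 13.5)

    def test_bump_becomes_nine_cell_mean(self):
        vals = np.full((8, 5, 9), 10.0)
        vals[0, 2, 4] += 9.0
        out = smooth_surfaces(SurfaceSet(vals, 1.0))
        assert out.values[0, 2, 4] == pytest.approx(11.0)

    def test_linear_ramp_unchanged_in_interior(self):
        ramp = np.add.outer(np.arange(6) * 2.0, np.arange(10) * 0.5)
        vals = np.tile(ramp, (8, 1, 1))
        out = smooth_surfaces(SurfaceSet(vals, 1.0))
        assert np.allclose(out.values[:, 1:-1, 1:-1], vals[:, 1:-1, 1:-1])


class TestEnforceOrdering:
    def test_ordered_input_fixed_point(self):
        vals = np.sort(np.random.default_rng(0).random((8, 2, 6)), axis=0)
        out = enforce_ordering(SurfaceSet(vals.copy(), 1.0))
        assert np.array_equal(out.values, vals)

    def test_dip_clamped_to_previous_boundary(self):
        vals = np.tile(np.arange(8, dtype=float)[:, None, None] * 5, (1, 1, 4)).copy()
        vals[3, 0, 2] = vals[2, 0, 2] - 2.0
        out = enforce_ordering(SurfaceSet(vals, 1.0))
        assert out.values[3, 0, 2] == vals[2, 0, 2]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_fuzzed_inputs_become_ordered(self, seed):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.random((8, 3, 8)) * 50, axis=0)
        noisy = base + rng.normal(0, 2, base.shape)
        out = enforce_ordering(SurfaceSet(noisy, 1.0))
        assert (np.diff(out.values, axis=0) >= 0).all()


class TestFullChain:
    def test_recovers_corrupted_phantom_within_one_pixel(self, bench_params):
        from octseg.app import corrupt_classmaps
        from octseg.metrics import boundary_mae

        vol, truths = generate_volume(bench_params)
        gt = volume_surfaces(truths)
        clean = [classmap_from_surfaces(t.surfaces, bench_params.image_height) for t in truths]
        corrupted = corrupt_classmaps(clean, np.random.default_rng(3))
        recovered = postprocess_maps(corrupted, bench_params.axial_scale)
        mae_px = boundary_mae(recovered, gt)["overall_mae"] / bench_params.axial_scale
        assert mae_px <= 1.0

    def test_idempotent_on_flat_surfaces(self):
        vals = np.tile(np.arange(8, dtype=float)[:, None, None] * 6 + 10, (1, 4, 12)).copy()
        surf = SurfaceSet(vals, 1.0)
        once = enforce_ordering(smooth_surfaces(interpolate_missing(remove_outliers(surf))))
        twice = enforce_ordering(smooth_surfaces(interpolate_missing(remove_outliers(once))))
        assert np.max(np.abs(twice.values - once.values)) <= 1e-9
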