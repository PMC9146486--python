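import dataclasses
import json

import numpy as np
import pytest

from octseg.phantom import (
    GroundTruth,
    PhantomParameterError,
    PhantomParams,
    RenderError,
    classmap_from_surfaces,
    collapse_labels,
    generate_dataset,
    generate_surfaces,
    generate_volume,
    render_bscan,
)
from octseg.types import BOUNDARY_NAMES, SurfaceSet


class TestGenerateSurfaces:
    def test_no_pit_no_jitter_gives_flat_parallel_surfaces(self, small_params):
        p = dataclasses.replace(small_params, foveal_pit_depth=0.0, thickness_jitter_sd=0.0)
        s = generate_surfaces(p, 3)
        # flat: no lateral variation at all
        assert np.allclose(np.ptp(s.values, axis=2), 0.0)
        # parallel at the cumulative mean thicknesses
        gaps_um = np.diff(s.values[:, 0, 0]) * p.axial_scale
        assert np.allclose(gaps_um, p.layer_thickness_means)

    def test_ordering_invariant(self, small_params):
        for b in range(small_params.n_bscans):
            s = generate_surfaces(small_params, b)
            assert (np.diff(s.values, axis=0) >= 0).all()

    def test_determinism_and_seed_sensitivity(self, small_params):
        a = generate_surfaces(small_params, 2)
        b = generate_surfaces(small_params, 2)
        assert np.array_equal(a.values, b.values)
        other = generate_surfaces(dataclasses.replace(small_params, seed=999), 2)
        assert not np.array_equal(a.values, other.values)

    def test_pit_pinches_inner_layers(self, small_params):
        s = generate_surfaces(small_params, small_params.fovea_center[0])
        xc = small_params.fovea_center[1]
        inner_center = (s.values[4, 0, xc] - s.values[0, 0, xc]) * small_params.axial_scale
        inner_edge = (s.values[4, 0, 3] - s.values[0, 0, 3]) * small_params.axial_scale
        assert inner_center < 0.5 * inner_edge

    def test_invalid_params_raise(self, small_params):
        with pytest.raises(PhantomParameterError):
            generate_surfaces(dataclasses.replace(small_params, image_height=0), 0)
        with pytest.raises(PhantomParameterError):
            generate_surfaces(
                dataclasses.replace(small_params, layer_thickness_means=(0.0,) * 7), 0
            )
        with pytest.raises(PhantomParameterError):
            generate_surfaces(
                dataclasses.replace(small_params, layer_reflectivity=(1.5,) * 9), 0
            )


class TestRenderBScan:
    def test_noiseless_render_is_piecewise_constant(self, small_params):
        p = dataclasses.replace(small_params, speckle_shape=0.0, blur_sigma=0.0)
        s = generate_surfaces(p, 1)
        img, gt = render_bscan(s, p, 1)
        refl = np.asarray(p.layer_reflectivity)
        assert np.array_equal(img.pixels, refl[gt.classmap9 - 1])

    def test_classmap_region_rule(self, small_params):
        s = generate_surfaces(small_params, 0)
        _, gt = render_bscan(s, small_params, 0)
        rows = np.arange(small_params.image_height)[:, None]
        expected = 1 + (rows >= s.values[:, 0, :][:, None, :]).sum(axis=0)
        assert np.array_equal(gt.classmap9, expected)

    def test_classmap3_is_collapse_of_classmap9(self, small_params):
        s = generate_surfaces(small_params, 0)
        _, gt = render_bscan(s, small_params, 0)
        assert np.array_equal(gt.classmap3, collapse_labels(gt.classmap9))

    def test_microcysts_change_only_inl_pixels(self, small_params):
        base = dataclasses.replace(small_params, speckle_shape=0.0, blur_sigma=0.0)
        with_cysts = dataclasses.replace(base, microcyst_rate=3.0)
        s = generate_surfaces(base, 3)
        img0, gt0 = render_bscan(s, base, 3)
        img1, gt1 = render_bscan(s, with_cysts, 3)
        assert np.array_equal(gt0.classmap9, gt1.classmap9)
        diff = img0.pixels != img1.pixels
        assert diff.any(), "expected at least one cyst at rate 3.0"
        assert (gt0.classmap9[diff] == 4).all()

    def test_render_determinism(self, small_params):
        s = generate_surfaces(small_params, 2)
        a, _ = render_bscan(s, small_params, 2)
        b, _ = render_bscan(s, small_params, 2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_out_of_bounds_surfaces_raise(self, small_params):
        s = generate_surfaces(small_params, 0)
        bad = SurfaceSet(s.values + 1000.0, s.axial_scale)
        with pytest.raises(RenderError):
            render_bscan(bad, small_params, 0)


class TestCollapseLabels:
    def test_all_vitreous(self):
        assert np.array_equal(collapse_labels(np.ones((4, 4), int)), np.ones((4, 4)))

    def test_mapping_table(self):
        cm = np.array([[1, 5, 9]])
        assert np.array_equal(collapse_labels(cm), np.array([[1, 2, 3]]))

    def test_pixel_count_conservation(self, small_params):
        s = generate_surfaces(small_params, 0)
        _, gt = render_bscan(s, small_params, 0)
        count3 = int((gt.classmap3 == 2).sum())
        count9 = sum(int((gt.classmap9 == k).sum()) for k in range(2, 9))
        assert count3 == count9

    def test_out_of_vocabulary_raises(self):
        with pytest.raises(ValueError):
            collapse_labels(np.array([[0, 1]]))
        with pytest.raises(ValueError):
            collapse_labels(np.array([[10]]))


class TestVolumeAndProperties:
    def test_classmap_reconstruction_matches_emitted(self, small_params):
        vol, truths = generate_volume(small_params)
        for t in truths:
            rebuilt = classmap_from_surfaces(t.surfaces, small_params.image_height)
            assert np.array_equal(rebuilt, t.classmap9)

    def test_all_classes_present_in_batch(self, small_params):
        _, truths = generate_volume(small_params)
        counts = np.zeros(10)
        for t in truths:
            counts += np.bincount(t.classmap9.ravel(), minlength=10)
        assert (counts[1:] > 0).all()


class TestGenerateDataset:
    def test_layout_and_counts(self, tmp_path, small_params):
        p = dataclasses.replace(small_params, n_bscans=5)
        out = tmp_path / "ds"
        manifest = generate_dataset(p, 2, out)
        pngs = sorted(out.rglob("bscan_*.png"))
        masks = sorted(out.rglob("mask9_*.png"))
        assert len(pngs) == 10 and len(masks) == 10
        assert (out / "manifest.json").exists()
        assert len(manifest["volumes"]) == 2
        for v in manifest["volumes"]:
            assert (out / v["id"] / "meta.json").exists()
            assert (out / v["id"] / "surfaces.csv").exists()

    def test_regeneration_is_byte_identical(self, tmp_path, small_params):
        p = dataclasses.replace(small_params, n_bscans=3)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(p, 1, a)
        generate_dataset(p, 1, b)
        fa = (a / "vol000" / "bscan_001.png").read_bytes()
        fb = (b / "vol000" / "bscan_001.png").read_bytes()
        assert fa == fb

    def test_nonempty_output_dir_rejected(self, tmp_path, small_params):
        out = tmp_path / "ds"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_dataset(small_params, 1, out)
        assert list(out.iterdir()) == [out / "existing.txt"]  # no partial write
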