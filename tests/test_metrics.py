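import numpy as np
import pytest

from octseg.metrics import boundary_mae, dice, icc_oneway, thickness_parameters
from octseg.types import SurfaceSet


class TestDice:
    def test_identical_maps(self):
        a = np.array([[1, 2], [3, 3]])
        assert all(v == 1.0 for v in dice(a, a).values())

    def test_disjoint_masks(self):
        a = np.full((4, 4), 1)
        b = np.full((4, 4), 2)
        d = dice(a, b)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_shifted_block_oracle(self):
        a = np.zeros((4, 6), int)
        b = np.zeros((4, 6), int)
        a[1:3, 1:3] = 1  # 2x2 block
        b[1:3, 2:4] = 1  # shifted one column: overlap 2 px
        assert dice(a, b)[1] == pytest.approx(2 * 2 / (4 + 4))

    def test_absent_class_defined_as_one(self):
        d = dice(np.zeros((2, 2), int), np.zeros((2, 2), int), classes=[5])
        assert d[5] == 1.0

    def test_symmetry(self, rng):
        a = rng.integers(1, 4, (8, 8))
        b = rng.integers(1, 4, (8, 8))
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBoundaryMAE:
    def _surf(self, vals, axial=3.87):
        return SurfaceSet(vals, axial_scale=axial)

    def test_identical_zero(self):
        vals = np.random.default_rng(0).random((8, 2, 5)) * 50
        r = boundary_mae(self._surf(vals), self._surf(vals.copy()))
        assert r["overall_mae"] == 0.0
        assert all(m == 0.0 and s == 0.0 for m, s in r["per_boundary"].values())

    def test_constant_offset(self):
        vals = np.full((8, 1, 4), 30.0)
        r = boundary_mae(self._surf(vals + 2.0), self._surf(vals))
        for m, s in r["per_boundary"].values():
            assert m == pytest.approx(2 * 3.87)
            assert s == pytest.approx(0.0)
        assert r["overall_mae"] == pytest.approx(7.74)

    def test_alternating_error(self):
        vals = np.full((8, 1, 6), 30.0)
        err = np.tile(np.array([1.0, -1.0]), 3)
        r = boundary_mae(self._surf(vals + err), self._surf(vals))
        for m, s in r["per_boundary"].values():
            assert m == pytest.approx(3.87)
            assert s == pytest.approx(0.0)

    def test_symmetry(self, rng):
        a = self._surf(rng.random((8, 2, 5)) * 40)
        b = self._surf(rng.random((8, 2, 5)) * 40)
        assert boundary_mae(a, b)["overall_mae"] == pytest.approx(
            boundary_mae(b, a)["overall_mae"]
        )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            boundary_mae(self._surf(np.zeros((8, 1, 4))), self._surf(np.zeros((8, 1, 5))))


class TestThicknessParameters:
    def _uniform_surfaces(self, tm_um=300.0, nb=21, na=21, axial=3.87):
        # ILM flat at 50 px; equally spaced boundaries summing to tm_um
        step_px = tm_um / axial / 7.0
        vals = 50.0 + np.arange(8)[:, None, None] * step_px * np.ones((8, nb, na))
        return SurfaceSet(vals, axial_scale=axial)

    def test_cylinder_arithmetic(self):
        surf = self._uniform_surfaces(300.0)
        # grid spacing 250 um in both directions -> 21 samples ~ 5 mm across
        params = thickness_parameters(surf, 250.0, 250.0, (10, 10), 5.0)
        assert params.thickness_um["TM"] == pytest.approx(300.0)
        assert params.volume_mm3["TM"] == pytest.approx(0.3 * np.pi * 2.5**2, rel=1e-6)

    def test_gcc_is_sum_of_mrnfl_and_gcipl(self, rng):
        vals = np.sort(rng.random((8, 9, 9)) * 100 + 20, axis=0)
        surf = SurfaceSet(vals, axial_scale=3.87)
        p = thickness_parameters(surf, 300.0, 300.0, (4, 4), 5.0)
        assert p.thickness_um["GCC"] == pytest.approx(
            p.thickness_um["mRNFL"] + p.thickness_um["GCIPL"]
        )

    def test_halving_region_preserves_uniform_mean_scales_volume(self):
        surf = self._uniform_surfaces(280.0)
        big = thickness_parameters(surf, 250.0, 250.0, (10, 10), 5.0)
        small = thickness_parameters(surf, 250.0, 250.0, (10, 10), 2.5)
        assert small.thickness_um["TM"] == pytest.approx(big.thickness_um["TM"])
        assert big.volume_mm3["TM"] / small.volume_mm3["TM"] == pytest.approx(4.0)

    def test_translation_invariance(self, rng):
        vals = np.sort(rng.random((8, 9, 9)) * 80 + 30, axis=0)
        a = thickness_parameters(SurfaceSet(vals, 3.87), 300.0, 300.0, (4, 4))
        b = thickness_parameters(SurfaceSet(vals + 17.0, 3.87), 300.0, 300.0, (4, 4))
        for k in a.thickness_um:
            assert a.thickness_um[k] == pytest.approx(b.thickness_um[k])

    def test_fovea_outside_grid_rejected(self):
        surf = self._uniform_surfaces()
        with pytest.raises(ValueError):
            thickness_parameters(surf, 250.0, 250.0, (99, 10))

    def test_incomplete_surfaces_rejected(self):
        surf = self._uniform_surfaces()
        surf.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            thickness_parameters(surf, 250.0, 250.0, (10, 10))


class TestICC:
    def test_perfect_reliability(self):
        data = np.array([[10, 10, 10], [20, 20, 20], [30, 30, 30]], float)
        icc, lo, hi = icc_oneway(data)
        assert icc == 1.0

    def test_pure_noise_nonpositive(self):
        rng = np.random.default_rng(0)
        data = 5.0 + rng.normal(0, 1, (12, 3))  # same true mean for every subject
        icc, _, _ = icc_oneway(data)
        assert icc <= 0.3  # no subject effect: ICC hovers at/below zero

    def test_matches_sums_of_squares_oracle(self, rng):
        data = rng.random((4, 3)) * 10

        # explicit one-way ANOVA decomposition
        n, k = data.shape
        grand = data.mean()
        msb = k * sum((row.mean() - grand) ** 2 for row in data) / (n - 1)
        msw = sum(((row - row.mean()) ** 2).sum() for row in data) / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)

        icc, lo, hi = icc_oneway(data)
        assert icc == pytest.approx(expected, abs=1e-9)
        assert lo <= icc <= hi

    def test_one_subject_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.array([[1.0, 2.0, 3.0]]))

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.array([[1.0], [2.0]]))
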