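import numpy as np
import pytest

from eemqda.core import EEMCube, WavelengthAxes
from eemqda.preprocess import (
    ScatterParams, excise_scatter, fill_masked, msc_correct, raman_emission_nm, scatter_mask,
)


def _cube(x, ex, em, mask=None):
    return EEMCube(np.asarray(x, float), WavelengthAxes(np.asarray(ex, float), np.asarray(em, float)), mask)


class TestScatterGeometry:
    def test_first_rayleigh_band_definition(self):
        # excitation 300 nm, halfwidth 10 -> emission in [290, 310] masked
        axes = WavelengthAxes(np.array([300.0]), np.arange(280.0, 331.0, 1.0))
        params = ScatterParams(rayleigh1_halfwidth_nm=10.0, rayleigh2_halfwidth_nm=0.0,
                               raman_halfwidth_nm=0.0)
        band = scatter_mask(axes, params)
        em = axes.emission_nm
        expected = (em >= 290.0) & (em <= 310.0)
        np.testing.assert_array_equal(band[0], expected)

    def test_raman_band_center_wavenumber_relation(self):
        # 1/(1/300 - 3400e-7) nm, evaluated by hand: 1/0.00299333... ~ 334.08
        assert raman_emission_nm(300.0, 3400.0) == pytest.approx(334.0757, abs=1e-3)

    def test_no_op_when_nothing_in_band(self):
        # emission far above every scatter ridge for ex=250 (2*ex=500, raman~273)
        cube = _cube(np.random.default_rng(0).random((2, 1, 5)), [250.0],
                     [700.0, 701.0, 702.0, 703.0, 704.0])
        out = excise_scatter(cube, ScatterParams())
        np.testing.assert_array_equal(out.intensities, cube.intensities)
        assert not out.mask.any()

    def test_idempotent(self, tiny_cohort):
        cube, _, _ = tiny_cohort
        once = excise_scatter(cube, ScatterParams())
        twice = excise_scatter(once, ScatterParams())
        np.testing.assert_array_equal(once.mask, twice.mask)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_error_when_whole_emission_vector_masked(self):
        axes = WavelengthAxes(np.array([300.0]), np.arange(295.0, 306.0, 1.0))
        cube = _cube(np.ones((1, 1, 11)), axes.excitation_nm, axes.emission_nm)
        with pytest.raises(ValueError, match="300"):
            excise_scatter(cube, ScatterParams(rayleigh1_halfwidth_nm=20.0))

    def test_below_rayleigh_region_zeroed_by_default(self):
        axes = WavelengthAxes(np.arange(250.0, 351.0, 10.0), np.arange(300.0, 851.0, 1.0))
        cube = EEMCube(np.ones((1, *axes.shape)), axes)
        out = excise_scatter(cube, ScatterParams())
        j = 10  # excitation 350: emission 300..337 lies below ex - halfwidth
        below = axes.emission_nm < 350.0 - 12.0
        inband = np.abs(axes.emission_nm - 350.0) <= 12.0
        assert np.all(out.intensities[0, j, below & ~out.mask[0, j]] == 0.0)
        assert out.mask[0, j, inband].all()


class TestFillMasked:
    def test_linear_segment(self):
        cube = _cube([[[1.0, 0.0, 3.0]]], [250.0], [300.0, 301.0, 302.0],
                     mask=np.array([[[False, True, False]]]))
        out = fill_masked(cube)
        assert out.intensities[0, 0, 1] == pytest.approx(2.0)
        assert out.mask is None

    def test_fully_observed_unchanged(self):
        x = np.random.default_rng(0).random((2, 2, 4))
        cube = _cube(x, [250.0, 260.0], [300.0, 301.0, 302.0, 303.0])
        out = fill_masked(cube)
        np.testing.assert_array_equal(out.intensities, x)

    def test_end_run_constant_extension(self):
        cube = _cube([[[1.0, 4.0, 0.0, 0.0]]], [250.0], [300.0, 301.0, 302.0, 303.0],
                     mask=np.array([[[False, False, True, True]]]))
        out = fill_masked(cube)
        np.testing.assert_allclose(out.intensities[0, 0], [1.0, 4.0, 4.0, 4.0])

    def test_unmasked_cells_bitwise_untouched(self, tiny_cohort):
        cube, _, _ = tiny_cohort
        excised = excise_scatter(cube, ScatterParams())
        filled = fill_masked(excised)
        obs = ~excised.mask
        np.testing.assert_array_equal(filled.intensities[obs], excised.intensities[obs])

    def test_too_few_observed_points(self):
        cube = _cube([[[1.0, 0.0, 0.0]]], [250.0], [300.0, 301.0, 302.0],
                     mask=np.array([[[False, True, True]]]))
        with pytest.raises(ValueError, match=">= 2"):
            fill_masked(cube)


class TestMsc:
    def _base(self, seed=0, n=4):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3, 7)) + 0.5
        return _cube(x, [250.0, 260.0, 270.0], np.arange(300.0, 307.0))

    def test_identity_when_equal_to_reference(self):
        cube = self._base()
        m = cube.unfold()[0]
        out, coef = msc_correct(cube.take(np.array([0])), reference=m)
        assert coef.offset[0] == pytest.approx(0.0, abs=1e-12)
        assert coef.slope[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.unfold()[0], m, atol=1e-12)

    def test_affine_family_collapses_to_reference(self):
        cube = self._base()
        m = cube.unfold()[0]
        distorted = EEMCube((2.0 * cube.intensities[:1] + 3.0), cube.axes)
        out, coef = msc_correct(distorted, reference=m)
        assert coef.offset[0] == pytest.approx(3.0, abs=1e-9)
        assert coef.slope[0] == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(out.unfold()[0], m, atol=1e-9)

    def test_idempotence_after_correction(self):
        cube = self._base(seed=3, n=6)
        out, coef = msc_correct(cube)
        again, coef2 = msc_correct(out, reference=coef.reference)
        np.testing.assert_allclose(coef2.offset, 0.0, atol=1e-9)
        np.testing.assert_allclose(coef2.slope, 1.0, atol=1e-9)

    def test_affine_inversion_arbitrary_reference(self):
        # MSC exactly inverts any per-sample affine distortion of the reference
        rng = np.random.default_rng(7)
        m = rng.random(21) + 1.0
        a = rng.normal(0, 2, size=5)
        b = rng.uniform(0.5, 3.0, size=5)
        x = a[:, None] + b[:, None] * m
        cube = _cube(x.reshape(5, 3, 7), [250.0, 260.0, 270.0], np.arange(300.0, 307.0))
        out, _ = msc_correct(cube, reference=m)
        np.testing.assert_allclose(out.unfold(), np.tile(m, (5, 1)), atol=1e-9)

    def test_requires_complete_cube(self):
        cube = self._base()
        cube.mask = np.zeros(cube.shape, bool)
        cube.mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="complete"):
            msc_correct(cube)

    def test_near_zero_slope_rejected(self):
        cube = self._base()
        flat = EEMCube(np.full_like(cube.intensities[:1], 5.0), cube.axes)
        with pytest.raises(ValueError, match="slope"):
            msc_correct(flat, reference=cube.unfold()[1])
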