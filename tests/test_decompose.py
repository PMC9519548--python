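import numpy as np
import pytest

from conftest import clean_spec, small_axes
from eemqda.core import EEMCube, WavelengthAxes
from eemqda.decompose import (
    congruence, explained_variance, load_model, match_factors, parafac_fit,
    project_scores, save_model, tucker3_fit,
)
from eemqda.synthetic import generate_cohort


def _axes(j=4, k=9):
    return WavelengthAxes(250.0 + 10.0 * np.arange(j), 300.0 + np.arange(k))


def _trilinear(A, B, C, axes):
    return EEMCube(np.einsum("if,jf,kf->ijk", A, B, C), axes)


class TestParafac:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(0)
        axes = _axes()
        a, b, c = rng.random(6) + 0.5, rng.random(4) + 0.5, rng.random(9) + 0.5
        cube = _trilinear(a[:, None], b[:, None], c[:, None], axes)
        m = parafac_fit(cube, 1)
        assert abs(congruence(m.B[:, 0], b)) >= 1 - 1e-10
        assert abs(congruence(m.C[:, 0], c)) >= 1 - 1e-10
        assert explained_variance(m) == pytest.approx(100.0, abs=1e-8)

    def test_rank3_recovery_from_generating_factors(self, rank3_fluorophores):
        spec = clean_spec(seed=5, fluorophores=rank3_fluorophores,
                          concentration_means=(1.0, 0.7, 0.9))
        cube, _, truth = generate_cohort(spec)
        m = parafac_fit(cube, 3)
        for est, true in ((m.B, truth.excitation_profiles), (m.C, truth.emission_profiles)):
            _, cong = match_factors(est, true)
            assert np.abs(cong).min() >= 0.999

    def test_score_matrix_shape(self):
        rng = np.random.default_rng(1)
        axes = _axes(3, 7)
        cube = EEMCube(rng.random((10, 3, 7)), axes)
        m = parafac_fit(cube, 2, max_iter=50)
        assert m.A.shape == (10, 2)

    def test_normalization_and_sign_convention(self):
        rng = np.random.default_rng(2)
        axes = _axes()
        cube = EEMCube(rng.random((6, 4, 9)), axes)
        m = parafac_fit(cube, 2)
        np.testing.assert_allclose(np.linalg.norm(m.B, axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(m.C, axis=0), 1.0, atol=1e-12)
        for M in (m.B, m.C):
            piv = np.argmax(np.abs(M), axis=0)
            assert (M[piv, np.arange(M.shape[1])] > 0).all()

    def test_two_runs_bit_identical(self):
        rng = np.random.default_rng(3)
        axes = _axes()
        cube = EEMCube(rng.random((6, 4, 9)), axes)
        m1 = parafac_fit(cube, 2)
        m2 = parafac_fit(cube, 2)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.B, m2.B)
        np.testing.assert_array_equal(m1.C, m2.C)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        axes = _axes()
        cube = EEMCube(rng.random((5, 4, 9)), axes)
        m = parafac_fit(cube, 3)
        resid = cube.intensities - m.reconstruct()
        assert float((resid**2).sum()) == pytest.approx(m.sse, rel=1e-6, abs=1e-10)

    def test_nonconvergence_flagged_not_raised(self):
        rng = np.random.default_rng(5)
        axes = _axes()
        cube = EEMCube(rng.random((6, 4, 9)), axes)
        m = parafac_fit(cube, 2, max_iter=2)
        assert m.converged is False

    def test_invalid_factor_count(self):
        axes = _axes()
        cube = EEMCube(np.ones((3, 4, 9)), axes)
        with pytest.raises(ValueError):
            parafac_fit(cube, 0)


class TestTucker3:
    def test_exact_orthogonal_model(self):
        rng = np.random.default_rng(0)
        axes = _axes(4, 9)
        A = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        B = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        C = np.linalg.qr(rng.standard_normal((9, 2)))[0]
        G = rng.standard_normal((2, 2, 2))
        cube = EEMCube(np.einsum("rst,ir,js,kt->ijk", G, A, B, C), axes)
        m = tucker3_fit(cube, (2, 2, 2))
        assert explained_variance(m) == pytest.approx(100.0, abs=1e-8)

    def test_rank1_core_is_product_of_factor_norms(self):
        rng = np.random.default_rng(1)
        axes = _axes()
        a, b, c = rng.random(5) + 0.5, rng.random(4) + 0.5, rng.random(9) + 0.5
        cube = _trilinear(a[:, None], b[:, None], c[:, None], axes)
        m = tucker3_fit(cube, (1, 1, 1))
        expected = np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c)
        assert abs(m.G[0, 0, 0]) == pytest.approx(expected, rel=1e-10)

    def test_sse_non_increasing_in_rank(self):
        rng = np.random.default_rng(2)
        axes = _axes(3, 8)
        cube = EEMCube(rng.random((6, 3, 8)), axes)
        sses = [tucker3_fit(cube, (r, r, r)).sse for r in (1, 2, 3)]
        assert sses[0] >= sses[1] >= sses[2]

    def test_orthonormal_factors(self):
        rng = np.random.default_rng(3)
        axes = _axes()
        cube = EEMCube(rng.random((6, 4, 9)), axes)
        m = tucker3_fit(cube, (2, 2, 2))
        for M in (m.A, m.B, m.C):
            np.testing.assert_allclose(M.T @ M, np.eye(2), atol=1e-10)

    def test_rank_bounds_checked(self):
        axes = _axes()
        cube = EEMCube(np.ones((3, 4, 9)), axes)
        with pytest.raises(ValueError):
            tucker3_fit(cube, (4, 4, 4))


class TestExplainedVariance:
    def test_zero_when_model_explains_nothing(self):
        from eemqda.decompose import ParafacModel

        rng = np.random.default_rng(5)
        axes = _axes(2, 2)
        cube = EEMCube(rng.random((3, 2, 2)), axes)
        total = float((cube.intensities**2).sum())
        null = ParafacModel(F=1, A=np.zeros((3, 1)), B=np.ones((2, 1)), C=np.ones((2, 1)),
                            sse=total, total_ss=total, n_iter=1, converged=True)
        assert explained_variance(null) == pytest.approx(0.0)
        assert explained_variance(null, cube) == pytest.approx(0.0)

    def test_all_zero_cube_rejected(self):
        axes = _axes(2, 2)
        m = parafac_fit(EEMCube(np.ones((3, 2, 2)), axes), 1)
        with pytest.raises(ValueError, match="all-zero"):
            explained_variance(m, EEMCube(np.zeros((3, 2, 2)), axes))

    def test_signal_noise_split_brute_force(self):
        rng = np.random.default_rng(6)
        axes = _axes()
        a, b, c = rng.random(8) + 0.5, rng.random(4) + 0.5, rng.random(9) + 0.5
        signal = np.einsum("i,j,k->ijk", a, b, c)
        noise = rng.normal(0, 0.01, signal.shape)
        cube = EEMCube(signal + noise, axes)
        m = parafac_fit(cube, 1)
        # independent oracle: direct summation of residual and total squares
        resid = cube.intensities - m.reconstruct()
        direct = 100.0 * (1.0 - (resid**2).sum() / (cube.intensities**2).sum())
        assert explained_variance(m) == pytest.approx(direct, abs=1e-8)


class TestProjection:
    def test_training_sample_reproduces_its_score_row(self):
        rng = np.random.default_rng(7)
        axes = _axes()
        cube = EEMCube(rng.random((8, 4, 9)), axes)
        for model in (parafac_fit(cube, 2), tucker3_fit(cube, (2, 2, 2))):
            S = project_scores(model, cube)
            assert np.abs(S - model.A).max() < 1e-8

    def test_noiseless_combination_recovers_weights(self):
        rng = np.random.default_rng(8)
        axes = _axes()
        cube = EEMCube(rng.random((8, 4, 9)), axes)
        m = parafac_fit(cube, 2)
        w = np.array([[1.5, -0.5], [0.2, 2.0]])
        new = EEMCube(np.einsum("if,jf,kf->ijk", w, m.B, m.C), axes)
        S = project_scores(m, new)
        np.testing.assert_allclose(S, w, atol=1e-8)

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(9)
        axes = _axes()
        cube = EEMCube(rng.random((6, 4, 9)), axes)
        m = parafac_fit(cube, 2)
        new = EEMCube(rng.random((3, 4, 9)), axes)
        S = project_scores(m, new)
        Z = m.basis()
        resid = new.unfold().T - Z @ S.T
        assert np.abs(Z.T @ resid).max() < 1e-8

    def test_axis_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        cube = EEMCube(rng.random((6, 4, 9)), _axes())
        m = parafac_fit(cube, 2)
        other = EEMCube(rng.random((2, 4, 5)), _axes(4, 5))
        with pytest.raises(ValueError, match="axes"):
            project_scores(m, other)


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    cube = EEMCube(rng.random((6, 4, 9)), _axes())
    for model in (parafac_fit(cube, 2), tucker3_fit(cube, (2, 2, 2))):
        path = tmp_path / "m.h5"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.A, model.A)
        np.testing.assert_array_equal(loaded.C, model.C)
        assert loaded.sse == model.sse
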