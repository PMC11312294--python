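import numpy as np
import pytest

from save_hsi.calibration import FeatureExpansion, apply_correction, expand_features
from save_hsi.colorimetry import ciede2000, spectrum_to_xyz, xyz_to_lab
from save_hsi.spectral import (
    DegenerateSpectraError,
    SpectralModel,
    TransformationMatrix,
    build_model,
    convert_image,
    convert_image_naive,
    fit_basis,
    fit_transformation,
    reconstruct_spectrum,
    spectral_rmse,
)


class TestFitBasis:
    def test_full_rank_explains_everything(self):
        rng = np.random.default_rng(0)
        spectra = rng.uniform(0, 1, (24, 401))  # generic, rank 23 after centering
        basis, _ = fit_basis(spectra, n_components=23)
        assert np.isclose(basis.explained_variance_ratio.sum(), 1.0, atol=1e-10)

    def test_six_components_capture_chart_variance(self, chart):
        spectra, _ = chart
        basis, _ = fit_basis(spectra, n_components=6)
        assert basis.explained_variance_ratio.sum() >= 0.99

    def test_identical_spectra_refused(self):
        spectra = np.tile(np.linspace(0.2, 0.8, 401), (24, 1))
        with pytest.raises(DegenerateSpectraError):
            fit_basis(spectra)

    def test_eigenvectors_orthonormal(self, chart):
        spectra, _ = chart
        basis, _ = fit_basis(spectra, n_components=6)
        gram = basis.eigenvectors @ basis.eigenvectors.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)

    def test_variance_ratios_non_increasing_and_bounded(self, chart):
        spectra, _ = chart
        basis, _ = fit_basis(spectra, n_components=8)
        evr = basis.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all((evr >= 0) & (evr <= 1)) and evr.sum() <= 1 + 1e-12

    def test_component_count_bounds(self, chart):
        spectra, _ = chart
        with pytest.raises(ValueError):
            fit_basis(spectra, n_components=0)
        with pytest.raises(ValueError):
            fit_basis(spectra, n_components=24)

    def test_components_beyond_rank_rejected(self, chart):
        # the synthetic chart is built from a limited primitive palette, so
        # its spectra span fewer than 23 directions
        spectra, _ = chart
        with pytest.raises(ValueError, match="rank"):
            fit_basis(spectra, n_components=23)

    def test_matches_sklearn_pca_oracle(self, chart):
        from sklearn.decomposition import PCA

        spectra, _ = chart
        basis, scores = fit_basis(spectra, n_components=6)
        oracle = PCA(n_components=6, svd_solver="full").fit(spectra)
        assert np.allclose(
            basis.explained_variance_ratio, oracle.explained_variance_ratio_, atol=1e-10
        )
        # principal directions agree up to sign
        for ours, theirs in zip(basis.eigenvectors, oracle.components_):
            assert min(
                np.max(np.abs(ours - theirs)), np.max(np.abs(ours + theirs))
            ) < 1e-8

    def test_scores_reproduce_centered_spectra_at_full_rank(self):
        rng = np.random.default_rng(1)
        spectra = rng.uniform(0, 1, (24, 401))
        basis, scores = fit_basis(spectra, n_components=23)
        rebuilt = basis.mean_spectrum + (basis.eigenvectors.T @ scores).T
        assert np.allclose(rebuilt, spectra, atol=1e-10)


class TestFitTransformation:
    def test_recovers_generating_matrix(self):
        rng = np.random.default_rng(0)
        exp = FeatureExpansion()
        xyz = rng.uniform(5, 90, (24, 3))
        V = expand_features(xyz, exp).T
        L = rng.normal(0, 1, (6, exp.dimension))
        scores = L @ V
        M = fit_transformation(scores, xyz, exp)
        assert np.allclose(M.entries @ V, scores, atol=1e-8)

    def test_zero_scores_give_zero_matrix(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(5, 90, (24, 3))
        M = fit_transformation(np.zeros((6, 24)), xyz, FeatureExpansion())
        assert np.allclose(M.entries, 0.0, atol=1e-12)

    def test_beats_constant_predictor(self, chart, default_capture, default_model):
        spectra, _ = chart
        _, scores = fit_basis(spectra, n_components=6)
        xyz_c = apply_correction(default_model.correction, default_capture.camera_xyz)
        M = fit_transformation(scores, xyz_c, default_model.expansion)
        V = expand_features(xyz_c, default_model.expansion).T
        fit_resid = np.sum((M.entries @ V - scores) ** 2)
        const_resid = np.sum((scores - scores.mean(axis=1, keepdims=True)) ** 2)
        assert fit_resid <= const_resid


class TestReconstruction:
    def test_zero_transformation_returns_mean_spectrum(self, default_model):
        model = SpectralModel(
            grid=default_model.grid,
            expansion=default_model.expansion,
            correction=default_model.correction,
            basis=default_model.basis,
            transformation=TransformationMatrix(
                entries=np.zeros_like(default_model.transformation.entries)
            ),
        )
        out = reconstruct_spectrum(model, (30.0, 40.0, 50.0))
        assert np.allclose(out, model.basis.mean_spectrum)

    def test_training_patches_reconstruct_below_point_one(
        self, chart, default_capture, default_model
    ):
        spectra, _ = chart
        xyz_c = apply_correction(default_model.correction, default_capture.camera_xyz)
        rec = reconstruct_spectrum(default_model, xyz_c)
        rmse = spectral_rmse(rec, spectra)
        assert np.sum(rmse < 0.1) >= 23

    def test_round_trip_color_error_small(
        self, chart, default_capture, default_model, illuminant, cmf, white
    ):
        xyz_c = apply_correction(default_model.correction, default_capture.camera_xyz)
        rec = reconstruct_spectrum(default_model, xyz_c)
        xyz_back = spectrum_to_xyz(rec, illuminant, cmf)
        de = ciede2000(
            xyz_to_lab(xyz_back, white),
            xyz_to_lab(default_capture.reference_xyz, white),
        )
        assert np.mean(de) < 2.0

    def test_output_clipped_to_physical_range(self, default_model):
        rng = np.random.default_rng(2)
        xyz = rng.uniform(0, 120, (100, 3))
        rec = reconstruct_spectrum(default_model, xyz)
        assert rec.min() >= 0.0 and rec.max() <= 1.2


class TestConvertImage:
    def test_flat_image_gives_identical_spectra(self, default_model):
        img = np.full((2, 2, 3), (120, 80, 200), dtype=np.uint8)
        cube = convert_image(default_model, img)
        flat = cube.intensities.reshape(4, -1)
        assert np.array_equal(flat[0], flat[1])
        assert np.array_equal(flat[0], flat[3])

    def test_white_image_round_trips_near_y100(
        self, identity_model, illuminant, cmf
    ):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        cube = convert_image(identity_model, img)
        xyz = spectrum_to_xyz(cube.intensities[0, 0], illuminant, cmf)
        assert abs(xyz[1] - 100.0) < 5.0

    def test_memoized_path_matches_naive_bitwise(self, default_model):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        fast = convert_image(default_model, img).intensities
        slow = convert_image_naive(default_model, img).intensities
        assert np.array_equal(fast, slow)

    def test_pixel_permutation_equivariance(self, default_model):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        perm = rng.permutation(64)
        cube = convert_image(default_model, img).intensities.reshape(64, -1)
        img_perm = img.reshape(64, 3)[perm].reshape(8, 8, 3)
        cube_perm = convert_image(default_model, img_perm).intensities.reshape(64, -1)
        assert np.array_equal(cube_perm, cube[perm])

    def test_non_uint8_rejected(self, default_model):
        with pytest.raises(ValueError):
            convert_image(default_model, np.zeros((4, 4, 3), dtype=float))


class TestSpectralRmse:
    def test_identical_spectra_zero(self):
        s = np.linspace(0, 1, 401)
        assert spectral_rmse(s, s) == 0.0

    def test_constant_offset(self):
        s = np.linspace(0, 1, 401)
        assert np.isclose(spectral_rmse(s, s + 0.07), 0.07)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, (10, 401))
        b = rng.uniform(0, 1, (10, 401))
        naive = np.array(
            [np.sqrt(sum((x - y) ** 2 for x, y in zip(ra, rb)) / 401) for ra, rb in zip(a, b)]
        )
        assert np.allclose(spectral_rmse(a, b), naive, atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(Exception):
            spectral_rmse(np.ones(401), np.ones(100))


class TestModelSerialization:
    def test_json_round_trip(self, default_model, tmp_path):
        path = tmp_path / "model.json"
        default_model.save(path)
        loaded = SpectralModel.load(path)
        assert loaded.expansion.terms == default_model.expansion.terms
        assert np.array_equal(loaded.correction.entries, default_model.correction.entries)
        assert np.array_equal(
            loaded.basis.eigenvectors, default_model.basis.eigenvectors
        )
        assert np.array_equal(
            loaded.transformation.entries, default_model.transformation.entries
        )
        xyz = (20.0, 30.0, 40.0)
        assert np.array_equal(
            reconstruct_spectrum(loaded, xyz), reconstruct_spectrum(default_model, xyz)
        )

    def test_unsupported_schema_version_rejected(self, default_model, tmp_path):
        text = default_model.to_json().replace('"schema_version": 1', '"schema_version": 99')
        with pytest.raises(ValueError, match="schema"):
            SpectralModel.from_json(text)
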