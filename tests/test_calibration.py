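"""Polynomial expansion, pseudo-inverse fits, PCA basis, reconstruction."""

import numpy as np
import pytest

import retispec as r
from retispec.calibration import (GammaDecode, PolynomialExpansion, expand,
                                  fit_basis, fit_correction, reconstruct_spectrum)
from retispec.core import Colorimetry

NO_DECODE = GammaDecode(kind="none")


class TestExpansion:
    @pytest.mark.parametrize("order,with_const,n", [(3, True, 20), (3, False, 19),
                                                    (1, True, 4), (2, True, 10)])
    def test_term_counts(self, order, with_const, n):
        assert PolynomialExpansion(order, with_const).n_terms == n

    def test_zero_triplet_activates_only_the_constant(self):
        e = PolynomialExpansion(order=3)
        v = expand(np.zeros(3), e)
        const_slot = e.term_list.index((0, 0, 0))
        expected = np.zeros(e.n_terms)
        expected[const_slot] = 1.0
        assert np.array_equal(v, expected)

    def test_terms_unique_and_degree_bounded(self):
        e = PolynomialExpansion(order=3)
        terms = e.term_list
        assert len(set(terms)) == len(terms) == 20
        assert all(sum(t) <= 3 for t in terms)


class TestCorrection:
    def test_exact_polynomial_system_reproduced_to_machine_precision(self, exact_patches):
        patch, M_true = exact_patches
        corr = fit_correction(patch, decode=NO_DECODE)
        assert corr.max_residual < 1e-8
        assert np.abs(corr.M - M_true).max() < 1e-6

    def test_pinv_matches_normal_equations_oracle(self, exact_patches):
        patch, _ = exact_patches
        corr = fit_correction(patch, decode=NO_DECODE)
        V = expand(patch.rgb, PolynomialExpansion()).T  # (T, N)
        A = patch.reference_xyz.T
        M_oracle = A @ V.T @ np.linalg.inv(V @ V.T)  # normal equations
        assert np.abs(corr.M - M_oracle).max() < 1e-8

    def test_duplicate_patches_leave_solution_unchanged(self, exact_patches):
        patch, _ = exact_patches
        corr = fit_correction(patch, decode=NO_DECODE)
        import dataclasses
        doubled = dataclasses.replace(
            patch,
            reflectance=np.vstack([patch.reflectance] * 2),
            reference_xyz=np.vstack([patch.reference_xyz] * 2),
            rgb=np.vstack([patch.rgb] * 2),
            patch_ids=np.arange(1, 49),
        )
        corr2 = fit_correction(doubled, decode=NO_DECODE)
        assert np.abs(corr.M - corr2.M).max() < 1e-8

    def test_refit_on_own_predictions_is_idempotent(self, exact_patches):
        import dataclasses
        patch, _ = exact_patches
        corr = fit_correction(patch, decode=NO_DECODE)
        predicted = expand(patch.rgb, PolynomialExpansion()) @ corr.M.T
        refit = fit_correction(dataclasses.replace(patch, reference_xyz=predicted),
                               decode=NO_DECODE)
        assert np.abs(corr.M - refit.M).max() < 1e-8


class TestBasis:
    def test_full_basis_reconstructs_training_spectra_exactly(self, patches):
        corr = fit_correction(patches)
        basis = fit_basis(patches, corr, k=24)
        centered = patches.reflectance - basis.mean_spectrum
        recon = basis.mean_spectrum + (centered @ basis.eigenvectors.T) @ basis.eigenvectors
        assert np.abs(recon - patches.reflectance).max() < 1e-8

    def test_eigenvectors_orthonormal(self, patches):
        corr = fit_correction(patches)
        basis = fit_basis(patches, corr, k=12)
        gram = basis.eigenvectors @ basis.eigenvectors.T
        assert np.allclose(gram, np.eye(12), atol=1e-10)

    def test_rank_one_spectra_explained_by_first_component(self, grid, cam):
        import dataclasses
        rng = np.random.default_rng(0)
        curve = rng.uniform(0.2, 0.8, grid.n_bands)
        scales = np.linspace(0.2, 1.0, 24)
        refl = scales[:, None] * curve
        cm = Colorimetry(grid=grid)
        p = r.ColorPatchSet(reflectance=refl, reference_xyz=cm.spectrum_to_xyz(refl),
                            grid=grid, colorimetry=cm)
        p = r.photograph_patches(p, cam)
        basis = fit_basis(p, fit_correction(p), k=3)
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_variance_nondecreasing_in_k(self, patches):
        corr = fit_correction(patches)
        totals = [fit_basis(patches, corr, k=k).explained_variance_ratio.sum()
                  for k in (2, 6, 12, 20)]
        assert np.all(np.diff(totals) >= -1e-12)

    def test_k_out_of_range_rejected(self, patches):
        corr = fit_correction(patches)
        with pytest.raises(ValueError):
            fit_basis(patches, corr, k=25)
        with pytest.raises(ValueError):
            fit_basis(patches, corr, k=0)


class TestReconstruction:
    def test_output_length_matches_grid(self, model):
        spec = reconstruct_spectrum(np.array([0.5, 0.4, 0.3]), model)
        assert spec.shape == (401,)

    def test_zero_scores_give_mean_spectrum(self, model):
        # a score_map of zeros makes reconstruction the mean spectrum exactly
        import copy
        m = copy.deepcopy(model)
        m.basis.score_map = np.zeros_like(m.basis.score_map)
        spec = reconstruct_spectrum(np.array([0.7, 0.2, 0.1]), m)
        assert np.allclose(spec, np.clip(m.basis.mean_spectrum, 0, 1.5))

    def test_exact_recovery_on_consistent_low_rank_target(self, grid):
        """Spectra whose scores are exactly polynomial in the camera triplet
        are recovered end to end to numerical precision."""
        rng = np.random.default_rng(11)
        exp3 = PolynomialExpansion(order=3)
        rgb = rng.uniform(0.1, 0.9, size=(24, 3))
        M_true = rng.normal(0, 0.2, size=(3, exp3.n_terms))
        xyz = expand(rgb, exp3) @ M_true.T
        k_true = 4
        eig, _ = np.linalg.qr(rng.normal(size=(grid.n_bands, k_true)))
        G = rng.normal(0, 0.05, size=(k_true, exp3.n_terms))
        scores = expand(xyz, exp3) @ G.T
        mean = np.full(grid.n_bands, 0.5)
        refl = mean + scores @ eig.T
        cm = Colorimetry(grid=grid)
        p = r.ColorPatchSet(reflectance=refl, reference_xyz=xyz, grid=grid,
                            colorimetry=cm, rgb=rgb)
        m = r.fit_calibration(p, k=24, decode=NO_DECODE, pinv_rcond=None)
        rec = reconstruct_spectrum(p.rgb, m)
        assert np.abs(rec - refl).max() < 1e-6

    def test_round_trip_beats_trivial_predictor(self, model, noise_free_cam, grid):
        """Spectrum -> camera -> reconstruction recovers fundus-like spectra
        substantially better than always predicting the target mean."""
        from retispec.synthetic import sample_deviation, tissue_spectra

        rng = np.random.default_rng(4)
        ts = tissue_spectra(grid)
        specs = np.array([
            0.75 * ts[0] + 0.18 * ts[1] + 0.07 * ts[2] + sample_deviation(rng, grid)
            for _ in range(40)
        ])
        rgb = r.render_rgb(specs, noise_free_cam)
        rec = reconstruct_spectrum(rgb, model)
        rmse = np.sqrt(((rec - specs) ** 2).mean())
        trivial = np.sqrt(((specs - model.basis.mean_spectrum) ** 2).mean())
        assert rmse < 0.6 * trivial


class TestEvaluate:
    def test_reference_against_itself_is_zero(self, patches, model):
        lab = model.colorimetry.spectrum_to_lab(patches.reflectance)
        assert np.allclose(r.ciede2000(lab, lab), 0.0)

    def test_ideal_target_evaluates_near_perfectly(self, grid):
        rng = np.random.default_rng(11)
        exp3 = PolynomialExpansion(order=3)
        rgb = rng.uniform(0.1, 0.9, size=(24, 3))
        M_true = rng.normal(0, 0.2, size=(3, exp3.n_terms))
        xyz = expand(rgb, exp3) @ M_true.T
        eig, _ = np.linalg.qr(rng.normal(size=(grid.n_bands, 4)))
        scores = expand(xyz, exp3) @ rng.normal(0, 0.05, size=(4, exp3.n_terms)).T
        refl = np.full(grid.n_bands, 0.5) + scores @ eig.T
        cm = Colorimetry(grid=grid)
        # reference XYZ must be colorimetrically consistent for the Lab step
        p = r.ColorPatchSet(reflectance=refl, reference_xyz=cm.spectrum_to_xyz(refl),
                            grid=grid, colorimetry=cm, rgb=rgb)
        m = r.fit_calibration(p, k=24, decode=NO_DECODE, pinv_rcond=None)
        rep = r.evaluate(m, p)
        assert rep.mean_de < 0.1
        assert rep.mean_de <= rep.max_de

    def test_camera_noise_degrades_mean_delta_e(self, grid):
        """Average training dE00 grows monotonically with sensor noise."""
        means = []
        for noise in (0.0, 0.02, 0.08):
            vals = []
            for seed in range(5):
                cam = r.default_camera(grid, noise_sd=noise, seed=seed)
                p = r.photograph_patches(r.make_colorchecker(grid, seed=1), cam,
                                         seed=seed)
                m = r.fit_calibration(p, k=12)
                vals.append(r.evaluate(m, p).mean_de)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
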