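"""Band-ratio regression, Theil's U, LOOCV, unmixing, raster prediction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foragemap.spectral import (
    LinearUnmixer,
    SRIRegressor,
    aggregate_plot_reflectance,
    evaluate_fit,
    fit_candidate,
    predict_raster,
    rank_sri,
    select_best,
    theils_u,
    unmix_lsu,
)
from foragemap.synthetic import default_endmember_library


class TestAggregate:
    def test_uniform_cube_returns_cell_spectrum(self):
        cube = np.full((5, 10, 10), 0.3)
        spec = aggregate_plot_reflectance(cube, (10.0, 10.0))
        assert np.allclose(spec, 0.3)

    def test_checkerboard_weighted_mean(self):
        cube = np.zeros((1, 6, 6))
        cube[0, ::2, ::2] = 1.0  # 1s on even-even cells
        spec = aggregate_plot_reflectance(cube, (5.0, 5.0))  # window rows 1-3
        window = cube[0, 1:4, 1:4]
        assert spec[0] == pytest.approx(window.mean())

    def test_off_edge_centre_rejected(self):
        cube = np.zeros((2, 5, 5))
        with pytest.raises(ValueError):
            aggregate_plot_reflectance(cube, (0.5, 0.5))


class TestRankSRI:
    def test_planted_linear_ratio_ranked_first(self):
        rng = np.random.default_rng(0)
        spectra = rng.uniform(0.1, 0.9, size=(20, 8))
        y = 3.0 + 2.0 * spectra[:, 5] / spectra[:, 2]
        ranked = rank_sri(spectra, y, top_n=100)
        assert (ranked.iloc[0]["i"], ranked.iloc[0]["j"]) == (5, 2)
        assert ranked.iloc[0]["r2"] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_noise(self):
        rng = np.random.default_rng(1)
        spectra = rng.uniform(0.1, 0.9, size=(20, 10))
        y = rng.normal(size=20)
        ranked = rank_sri(spectra, y, top_n=1)
        best_r2 = -1.0
        for i, j in itertools.permutations(range(10), 2):
            r = np.corrcoef(spectra[:, i] / spectra[:, j], y)[0, 1] ** 2
            best_r2 = max(best_r2, r)
        assert ranked.iloc[0]["r2"] == pytest.approx(best_r2)

    def test_candidate_count_ordered_pairs(self):
        rng = np.random.default_rng(2)
        spectra = rng.uniform(0.1, 0.9, size=(10, 10))
        y = rng.normal(size=10)
        ranked = rank_sri(spectra, y, top_n=10_000)
        assert len(ranked) == 90

    def test_zero_variance_response_rejected(self):
        spectra = np.random.default_rng(3).uniform(0.1, 1, (10, 4))
        with pytest.raises(ValueError):
            rank_sri(spectra, np.ones(10))

    def test_zero_denominator_pairs_excluded(self):
        rng = np.random.default_rng(4)
        spectra = rng.uniform(0.1, 0.9, size=(12, 5))
        spectra[3, 2] = 0.0
        ranked = rank_sri(spectra, rng.normal(size=12), top_n=100)
        assert not ((ranked["j"] == 2)).any()
        assert ranked.attrs["n_excluded"] == 4


class TestFitCandidate:
    def test_exact_linear_zero_loocv_residuals(self):
        x = np.linspace(1, 5, 10)
        y = 2.0 + 3.0 * x
        cand = fit_candidate(x, y, "linear")
        assert np.allclose(cand.loocv_pred, y, atol=1e-8)

    def test_loocv_identity_matches_explicit_refits(self):
        """Leverage-identity LOOCV equals brute-force n-1 refitting."""
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 5, 25)
        y = 1 + 2 * x + rng.normal(0, 0.5, 25)
        for form in ("linear", "polynomial2"):
            cand = fit_candidate(x, y, form)
            mask = np.ones(25, dtype=bool)
            from foragemap.spectral import _apply_form

            for i in range(25):
                mask[i] = False
                sub = fit_candidate(x[mask], y[mask], form)
                pred = _apply_form(form, sub.coefficients, np.array([x[i]]))[0]
                assert cand.loocv_pred[i] == pytest.approx(pred, rel=1e-6)
                mask[i] = True

    def test_exact_quadratic_beats_linear_on_aic(self):
        x = np.linspace(0, 4, 15)
        y = 1.0 + 0.5 * x + 2.0 * x ** 2
        aic_quad = fit_candidate(x, y, "polynomial2").aic
        aic_lin = fit_candidate(x, y, "linear").aic
        assert aic_quad < aic_lin

    def test_exponential_recovers_planted_coefficients(self):
        x = np.linspace(0.5, 3, 20)
        y = 2.0 * np.exp(0.8 * x)
        cand = fit_candidate(x, y, "exponential")
        assert cand.coefficients[0] == pytest.approx(2.0, rel=1e-5)
        assert cand.coefficients[1] == pytest.approx(0.8, rel=1e-5)

    def test_exponential_skipped_on_nonpositive_response(self):
        x = np.linspace(1, 5, 10)
        y = np.linspace(-1, 8, 10)
        with pytest.warns(UserWarning):
            assert fit_candidate(x, y, "exponential") is None

    def test_sample_size_preconditions(self):
        x = np.arange(5.0) + 1
        y = 2 * x
        assert fit_candidate(x, y, "polynomial2") is not None
        with pytest.raises(ValueError):
            fit_candidate(x[:3], y[:3], "polynomial2")


class TestTheilsU:
    def test_perfect_agreement_zero(self):
        assert theils_u([1, 2, 3], [1, 2, 3]) == 0.0

    def test_sign_flip_is_one(self):
        o = np.array([1.0, -2.0, 3.0])
        assert theils_u(o, -o) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        u = theils_u([1, 2, 3], [2, 3, 4])
        expected = 1.0 / (np.sqrt(14 / 3) + np.sqrt(29 / 3))
        assert u == pytest.approx(expected, abs=1e-12)
        assert u == pytest.approx(0.190, abs=5e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            theils_u([0.0, 0.0], [0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=12),
        st.floats(0.01, 100.0),
    )
    def test_bounds_and_scale_invariance(self, obs, scale):
        rng = np.random.default_rng(0)
        o = np.asarray(obs)
        p = o + rng.normal(0, 1.0, len(o))
        if np.sqrt(np.mean(o ** 2)) + np.sqrt(np.mean(p ** 2)) == 0:
            return
        u = theils_u(o, p)
        assert 0.0 <= u <= 1.0 + 1e-12
        assert theils_u(scale * o, scale * p) == pytest.approx(u, rel=1e-9)


class TestEvaluateFit:
    def test_perfect_predictions(self):
        stats = evaluate_fit([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert stats.rmse == 0.0 and stats.adj_r2 == 1.0

    def test_pct_within_matches_direct_count(self):
        o = np.full(10, 2.0)
        p = np.array([2.1] * 6 + [3.0] * 4)
        stats = evaluate_fit(o, p)
        direct = 100.0 * np.mean(np.abs(p - o) < 0.2 * np.abs(o))
        assert stats.pct_within_20pct_rmse == pytest.approx(direct) == 60.0
        rmse_stats = evaluate_fit(o, p, pct_mode="rmse")
        direct_rmse = 100.0 * np.mean(np.abs(p - o) < 0.2 * rmse_stats.rmse)
        assert rmse_stats.pct_within_20pct_rmse == pytest.approx(direct_rmse)

    def test_constant_predictions_flagged_degenerate(self):
        stats = evaluate_fit([1.0, 2, 3], [2.0, 2, 2])
        assert stats.degenerate and stats.adj_r2 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_fit([1, 2], [1, 2, 3])


class TestSelectBest:
    def _model(self, aic, u=0.1, ncoef=2):
        from foragemap.spectral import FitStats, SRIModel

        return SRIModel(
            response="biomass", band_pair=(0, 1), form="linear",
            coefficients=(0.0,) * ncoef,
            stats=FitStats(u, 0.9, 1.0, 80.0, aic),
        )

    def test_single_candidate(self):
        m = self._model(10.0)
        assert select_best([m]) is m

    def test_aic_tie_broken_by_theils_u(self):
        a = self._model(5.0, u=0.3)
        b = self._model(5.0, u=0.1)
        assert select_best([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestSRIRegressorRecovery:
    def test_planted_pair_and_form_selected(self, pure_scene, plot_table):
        cfg = pure_scene.config
        reg = SRIRegressor(response="biomass", top_n=20)
        reg.fit(plot_table, plot_table["biomass"].to_numpy())
        assert reg.band_pair_ == cfg.biomass_band_pair
        assert reg.form_ == cfg.biomass_relation[0]

    def test_predict_close_to_truth(self, pure_scene, plot_table):
        reg = SRIRegressor(response="biomass", top_n=20)
        y = plot_table["biomass"].to_numpy()
        reg.fit(plot_table, y)
        pred = reg.predict(plot_table)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.99


class TestUnmixing:
    def test_pure_grass_pixel(self):
        lib = default_endmember_library(12)
        cube = lib[0].reshape(-1, 1, 1)
        fractions, mask = unmix_lsu(cube, lib)
        assert fractions[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert mask[0, 0]

    def test_known_mixture_recovered(self):
        lib = default_endmember_library(12)
        mix = 0.3 * lib[0] + 0.7 * lib[2]
        fractions, mask = unmix_lsu(mix.reshape(-1, 1, 1), lib)
        assert fractions[0, 0, 0] == pytest.approx(0.3, abs=1e-6)
        assert fractions[2, 0, 0] == pytest.approx(0.7, abs=1e-6)
        assert not mask[0, 0]

    def test_half_grass_boundary_included(self):
        lib = default_endmember_library(12)
        mix = 0.5 * lib[0] + 0.5 * lib[2]
        _, mask = unmix_lsu(mix.reshape(-1, 1, 1), lib)
        assert mask[0, 0]

    def test_fractions_on_simplex_and_beat_vertices(self, mixed_scene):
        lib = mixed_scene.endmember_spectra
        sub = mixed_scene.cube[:, ::10, ::10]
        fractions, _ = unmix_lsu(sub, lib)
        s = fractions.sum(axis=0)
        assert np.allclose(s, 1.0, atol=1e-6) and fractions.min() >= -1e-12
        # residual no worse than any pure-endmember solution
        R = sub.reshape(sub.shape[0], -1)
        F = fractions.reshape(fractions.shape[0], -1)
        resid = np.linalg.norm(lib.T @ F - R, axis=0)
        for e in range(lib.shape[0]):
            vert = np.linalg.norm(lib[e][:, None] - R, axis=0)
            assert np.all(resid <= vert + 1e-9)

    def test_collinear_endmembers_rejected(self):
        lib = default_endmember_library(10)
        lib[1] = 2.0 * lib[0]
        with pytest.raises(ValueError, match="collinear|rank"):
            unmix_lsu(np.zeros((10, 1, 1)), lib)

    def test_transformer_interface(self, mixed_scene):
        um = LinearUnmixer().fit(mixed_scene.endmember_spectra)
        fr = um.transform(mixed_scene.cube[:, :5, :5])
        assert fr.shape == (5, 5, 5)


class TestPredictRaster:
    def test_uniform_cube_constant_raster(self, plot_table, pure_scene):
        reg = SRIRegressor(response="biomass", top_n=5)
        reg.fit(plot_table, plot_table["biomass"].to_numpy())
        i, j = reg.band_pair_
        cube = np.full((pure_scene.config.n_bands, 4, 4), 0.4)
        cube[i] = 0.2
        raster = predict_raster(reg, cube, np.ones((4, 4), bool))
        vals = raster.layer("biomass")
        assert np.allclose(vals, vals[0, 0])

    def test_noise_free_scene_inverts_planted_construction(self):
        """Applying the planted model to the noise-free cube recovers the
        true field exactly (construction inversion); the fitted model is
        close, limited only by 3x3 window averaging under a curved relation."""
        from foragemap.spectral import FitStats, SRIModel
        from foragemap.synthetic import SceneConfig, generate_scene, sample_plots

        scene = generate_scene(
            SceneConfig(n_rows=40, n_cols=40, n_bands=12, noise_sd=0.0,
                        pure_grass=True, grass_variability=0.0, seed=8)
        )
        cfg = scene.config
        planted = SRIModel(
            response="nitrogen", band_pair=cfg.n_band_pair,
            form=cfg.n_relation[0], coefficients=cfg.n_relation[1],
            stats=FitStats(0, 1, 0, 100, 0),
        )
        mask = np.ones(scene.biomass.shape, bool)
        raster = predict_raster(planted, scene.cube, mask)
        assert np.nanmax(np.abs(raster.layer("nitrogen") - scene.nitrogen)) < 1e-6

        plots = sample_plots(scene, 40, seed=1)
        reg = SRIRegressor(response="nitrogen", top_n=10)
        reg.fit(plots, plots["nitrogen"].to_numpy())
        fitted = predict_raster(reg, scene.cube, mask)
        assert np.nanmax(np.abs(fitted.layer("nitrogen") - scene.nitrogen)) < 1e-3

    def test_masked_cells_are_nodata(self, plot_table, pure_scene):
        reg = SRIRegressor(response="biomass", top_n=5)
        reg.fit(plot_table, plot_table["biomass"].to_numpy())
        mask = np.zeros((10, 10), bool)
        mask[:3] = True
        cube = np.full((pure_scene.config.n_bands, 10, 10), 0.4)
        raster = predict_raster(reg, cube, mask)
        vals = raster.layer("biomass")
        assert np.isnan(vals[~mask]).all() and np.isfinite(vals[mask]).all()

    def test_band_pair_outside_cube_rejected(self, plot_table):
        reg = SRIRegressor(response="biomass", top_n=5)
        reg.fit(plot_table, plot_table["biomass"].to_numpy())
        small = np.zeros((2, 3, 3))
        with pytest.raises(ValueError):
            predict_raster(reg, small, np.ones((3, 3), bool))
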