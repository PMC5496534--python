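"""AICc arithmetic, candidate-set enumeration, and mixed-model fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from songnoise import (
    ModelSetConfig,
    ModelSpec,
    SimConfig,
    aicc,
    akaike_weights,
    build_model_set,
    covariation_test,
    default_amplitude_config,
    default_minfreq_config,
    evidence_ratio,
    fit_mixed_model,
    fit_model_set,
    parameter_importance,
    residual_diagnostics,
    simulate_study,
)


class TestAicc:
    def test_closed_form(self):
        # -2(-100) + 2*3 + 2*3*4/(20-3-1) = 207.5
        assert aicc(-100, 3, 20) == pytest.approx(207.5)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100, 3, 10 ** 9) == pytest.approx(206.0, abs=1e-6)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            aicc(-100, 3, 4)


class TestWeights:
    def test_two_equal_models(self):
        np.testing.assert_allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_sum_to_one(self):
        rng = np.random.default_rng(0)
        w = akaike_weights(rng.uniform(100, 130, 25))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rank_invariant_to_constant_shift(self):
        a = np.array([100.0, 103.0, 110.0])
        w1 = akaike_weights(a)
        w2 = akaike_weights(a + 57.3)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_delta_formula(self):
        w = akaike_weights([100.0, 102.0])
        assert w[1] / w[0] == pytest.approx(np.exp(-1.0))


class TestEvidenceRatio:
    def test_equal_weights(self):
        assert evidence_ratio(0.4, 0.4) == 1.0

    def test_zero_null_is_inf(self):
        assert evidence_ratio(0.5, 0.0) == np.inf

    def test_matches_delta_aicc_form(self):
        w = akaike_weights([100.0, 119.5])
        assert evidence_ratio(w[0], w[1]) == pytest.approx(np.exp(19.5 / 2), rel=1e-9)


class TestBuildModelSet:
    def test_power_set_of_three_additive_terms(self):
        cfg = ModelSetConfig(response="y", quadratics=False, interactions=False)
        specs = build_model_set(cfg)
        assert len(specs) == 8  # power set incl. the null

    def test_null_always_present(self):
        for cfg in (default_amplitude_config(), default_minfreq_config()):
            names = [s.name for s in build_model_set(cfg)]
            assert "Intercept only (null) model" in names

    def test_amplitude_set_contains_field_top_model(self):
        names = [s.name for s in build_model_set(default_amplitude_config())]
        assert "Distance + Instantaneous + Instantaneous^2" in names
        assert "Distance + Instantaneous^2 + Territory" in names  # quad w/o linear

    def test_minfreq_set_contains_single_noise_models(self):
        names = [s.name for s in build_model_set(default_minfreq_config())]
        for expected in ("Bout Background", "Territory", "Bout Background + Territory"):
            assert expected in names

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty term pool"):
            build_model_set(ModelSetConfig(response="y", noise_terms=()))


class TestFitMixedModel:
    def _flat_data(self, n_birds=6, n_per=10, seed=0):
        """Zero bird-level variance: the LMM should reduce to OLS."""
        rng = np.random.default_rng(seed)
        n = n_birds * n_per
        df = pd.DataFrame(
            {
                "bird_id": np.repeat([f"b{i}" for i in range(n_birds)], n_per),
                "instantaneous": rng.uniform(30, 54, n),
                "distance": rng.uniform(2, 16, n),
            }
        )
        df["song_amplitude"] = (
            80.0 + 0.3 * df.instantaneous + 0.14 * df.distance + rng.normal(0, 1.0, n)
        )
        return df

    def test_matches_ols_when_no_bird_variance(self):
        df = self._flat_data()
        spec = ModelSpec("song_amplitude", ("distance", "instantaneous"))
        fit = fit_mixed_model(df, spec)
        X = sm.add_constant(df[["distance", "instantaneous"]])
        ols = sm.OLS(df.song_amplitude, X).fit()
        assert fit.coefficients["distance"] == pytest.approx(
            ols.params["distance"], abs=1e-4
        )
        assert fit.coefficients["instantaneous"] == pytest.approx(
            ols.params["instantaneous"], abs=1e-4
        )

    def test_k_counts_all_parameters(self):
        df = self._flat_data()
        null = fit_mixed_model(df, ModelSpec("song_amplitude", ()))
        one = fit_mixed_model(df, ModelSpec("song_amplitude", ("instantaneous",)))
        assert null.k == 3  # intercept + bird variance + residual
        assert one.k == 4

    def test_single_bird_errors(self):
        df = self._flat_data(n_birds=1)
        with pytest.raises(ValueError, match="2 birds"):
            fit_mixed_model(df, ModelSpec("song_amplitude", ()))

    def test_missing_column_errors(self):
        df = self._flat_data().drop(columns=["distance"])
        with pytest.raises(ValueError, match="missing columns"):
            fit_mixed_model(df, ModelSpec("song_amplitude", ("distance",)))

    def test_random_slope_structure_counts_covariances(self):
        _, amp, _, _ = simulate_study(SimConfig(seed=3, n_birds=10, songs_per_bird=[8] * 10))
        spec = ModelSpec("song_amplitude", ("instantaneous",), random="slope",
                         slope_term="bout_background")
        fit = fit_mixed_model(amp, spec)
        # 2 fixed + 3 random (co)variances + residual
        assert fit.k == 6

    def test_parameter_recovery_within_2se(self):
        """Known generating coefficients recovered within 2 SE at modest n."""
        hits = 0
        for seed in range(8):
            _, amp, _, _ = simulate_study(
                SimConfig(seed=seed, n_birds=30, songs_per_bird=[8] * 30)
            )
            spec = ModelSpec(
                "song_amplitude", ("distance", "instantaneous", "instantaneous^2")
            )
            fit = fit_mixed_model(amp, spec)
            ok = all(
                abs(fit.coefficients[t] - truth) <= 2 * fit.std_errors[t]
                for t, truth in [
                    ("distance", 0.14),
                    ("instantaneous", -1.6),
                    ("instantaneous^2", 0.022),
                ]
            )
            hits += ok
        assert hits >= 6  # ~95% coverage per coefficient


class TestRanking:
    def test_weights_sum_to_one_and_top_delta_zero(self, sim_tables):
        _, amp, _, _ = sim_tables
        res = fit_model_set(
            amp,
            ModelSetConfig(
                response="song_amplitude",
                explicit_models=((), ("instantaneous",), ("distance",)),
            ),
        )
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.table["dAICc"].iloc[0] == 0.0

    def test_parameter_importance(self, sim_tables):
        _, amp, _, _ = sim_tables
        res = fit_model_set(
            amp,
            ModelSetConfig(
                response="song_amplitude",
                explicit_models=((), ("instantaneous",), ("instantaneous", "distance")),
            ),
        )
        w_inst = parameter_importance(res, "instantaneous")
        in_models = [f.spec.contains("instantaneous") for f in res.fits]
        assert w_inst == pytest.approx(res.weights[np.array(in_models)].sum())
        assert 0.0 <= w_inst <= 1.0

    def test_term_in_every_model_importance_one(self, sim_tables):
        _, amp, _, _ = sim_tables
        res = fit_model_set(
            amp,
            ModelSetConfig(
                response="song_amplitude",
                explicit_models=(("instantaneous",), ("instantaneous", "distance")),
            ),
        )
        # null is auto-added, so drop it from the check set
        w = parameter_importance(res, "instantaneous")
        null_w = res.weight_of("Intercept only (null) model")
        assert w == pytest.approx(1.0 - null_w)

    def test_absent_term_importance_zero_with_warning(self, sim_tables):
        _, amp, _, _ = sim_tables
        res = fit_model_set(
            amp,
            ModelSetConfig(
                response="song_amplitude", explicit_models=((), ("instantaneous",))
            ),
        )
        with pytest.warns(UserWarning):
            assert parameter_importance(res, "territory") == 0.0


class TestCovariation:
    def test_null_wins_when_no_effect(self, sim_tables):
        _, amp, mf, _ = sim_tables
        res = covariation_test(mf, amp)
        assert set(res.table["model"]) == {
            "Intercept only (null) model",
            "Song Amplitude",
        }

    def test_strong_effect_detected(self):
        _, amp, mf, _ = simulate_study(
            SimConfig(seed=9, n_birds=12, songs_per_bird=[6] * 12)
        )
        mf = mf.copy()
        # impose a strong amplitude -> min-freq coupling (plus scatter)
        rng = np.random.default_rng(10)
        mf["min_freq"] = (
            1000.0
            + 40.0 * amp["song_amplitude"].to_numpy()
            + rng.normal(0, 30.0, len(mf))
        )
        res = covariation_test(mf, amp)
        assert res.top.spec.name == "Song Amplitude"

    def test_mismatched_ids_error(self, sim_tables):
        _, amp, mf, _ = sim_tables
        amp = amp.copy()
        amp["song_id"] = "zz_" + amp["song_id"]
        with pytest.raises(ValueError, match="no songs shared"):
            covariation_test(mf, amp)


class TestDiagnostics:
    def test_homoscedastic_data_in_null_range(self, sim_tables):
        _, amp, _, _ = sim_tables
        fit = fit_mixed_model(
            amp, ModelSpec("song_amplitude", ("distance", "instantaneous", "instantaneous^2"))
        )
        d = residual_diagnostics(fit)
        assert abs(d.trend_slope) < 0.5
        assert 0.5 < d.spread_ratio < 2.0
        assert d.normality_p > 0.001

    def test_heteroscedastic_data_elevates_spread_ratio(self):
        rng = np.random.default_rng(21)
        n = 400
        df = pd.DataFrame(
            {
                "bird_id": np.repeat([f"b{i}" for i in range(20)], 20),
                "instantaneous": rng.uniform(30, 54, n),
            }
        )
        mu = 1.0 * df.instantaneous
        df["song_amplitude"] = mu + rng.normal(0, 0.15 * mu, n)  # sd grows with mean
        fit = fit_mixed_model(df, ModelSpec("song_amplitude", ("instantaneous",)))
        d = residual_diagnostics(fit)
        assert d.spread_ratio > 1.15

    def test_unconverged_fit_rejected(self, sim_tables):
        _, amp, _, _ = sim_tables
        fit = fit_mixed_model(amp, ModelSpec("song_amplitude", ()))
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            residual_diagnostics(fit)
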