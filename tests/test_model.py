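"""The full selection search and the fitted Model/Results objects."""

import numpy as np
import pandas as pd
import pytest

from lncsurv import (
    GammaConfig,
    InputError,
    MlrLDAcp,
    build_led,
    build_survival_vector,
    differential_screen,
    initialize_selection,
    model_significance,
    run_search,
    stagnation_kick,
)


@pytest.fixture(scope="module")
def fitted(strong_cohort):
    model = MlrLDAcp.from_cohort(strong_cohort.normal, strong_cohort.tumor,
                                 strong_cohort.clinical)
    return model, model.fit()


class TestInitializeSelection:
    def test_threshold_counts_population(self):
        p = np.concatenate([np.full(107, 1e-15), np.linspace(1e-10, 1e-4, 374)])
        x0, theta = initialize_selection(p, 1e-12)
        assert theta == 107
        assert set(np.flatnonzero(x0) + 1) == set(range(1, 108))

    def test_vacuous_threshold_sets_all_bits(self):
        p = np.linspace(1e-6, 0.9, 20)
        x0, theta = initialize_selection(p, 1.0)
        assert theta == 20 and x0.sum() == 20

    def test_fallback_seed_when_nothing_clears_threshold(self):
        p = np.linspace(1e-6, 0.9, 50)
        with pytest.warns(UserWarning, match="seeding"):
            x0, theta = initialize_selection(p, 1e-12)
        assert theta == x0.sum() == 10  # max(10, 50 // 10)
        assert x0[:10].all()  # the smallest P values sit first


class TestStagnationKick:
    def test_identical_leading_bits_flip(self):
        x = np.array([1, 0, 1, 0], dtype=np.uint8)
        out = stagnation_kick(x, x.copy(), theta=3)
        assert out.tolist() == [0, 1, 0, 0]

    def test_differing_leading_bits_untouched(self):
        x = np.array([1, 0, 1, 0], dtype=np.uint8)
        prev = np.array([0, 0, 1, 0], dtype=np.uint8)
        assert stagnation_kick(x, prev, theta=3).tolist() == x.tolist()

    def test_flip_then_correct_respects_cap(self, rng):
        from lncsurv import gamma_correct

        for _ in range(20):
            x = rng.integers(0, 2, size=30).astype(np.uint8)
            kicked = stagnation_kick(x, x.copy(), theta=7)
            assert gamma_correct(kicked, 7).sum() <= 7


class TestSearch:
    def test_parameter_recovery_with_strong_signal(self, strong_cohort, fitted):
        _, res = fitted
        causal = set(strong_cohort.truth["causal_transcripts"])
        recovered = causal & set(res.selected_ids)
        assert len(recovered) >= 0.9 * len(causal)
        for t in recovered:
            err = abs(res.theta[t] - strong_cohort.truth["coefficients"][t])
            assert err < 3 * res.bse[t]

    def test_bulletin_board_keeps_running_minimum(self, fitted):
        _, res = fitted
        aics = [r.stepwise_aic for r in res.trace if r.stepwise_aic is not None]
        assert res.aic_optimal == min(aics)
        assert res.aic_optimal <= aics[0]  # seed reduction never beats the board

    def test_residuals_orthogonal_to_selected_columns(self, fitted):
        model, res = fitted
        X = model.exog[list(res.selected_ids)].to_numpy()
        dots = X.T @ res.resid
        scale = np.abs(X).sum(axis=0) * np.abs(res.resid).max()
        assert (np.abs(dots) <= 1e-8 * np.maximum(scale, 1.0)).all()

    def test_search_is_deterministic(self, strong_cohort):
        kwargs = dict(normal=strong_cohort.normal, tumor=strong_cohort.tumor,
                      clinical=strong_cohort.clinical)
        r1 = MlrLDAcp.from_cohort(**kwargs).fit()
        r2 = MlrLDAcp.from_cohort(**kwargs).fit()
        assert r1.selected_ids == r2.selected_ids
        pd.testing.assert_series_equal(r1.theta, r2.theta)

    def test_zero_iterations_fits_seed_reduction(self, strong_cohort):
        c = strong_cohort
        ranking = differential_screen(c.normal, c.tumor)
        led = build_led(c.tumor, ranking)
        la = build_survival_vector(c.clinical, led.index)
        res = run_search(led, la, ranking, GammaConfig(D=0))
        assert res.delta > 0
        assert res.aic_optimal == res.trace[0].stepwise_aic

    def test_mismatched_response_length_rejected(self, strong_cohort):
        c = strong_cohort
        ranking = differential_screen(c.normal, c.tumor)
        led = build_led(c.tumor, ranking)
        with pytest.raises(InputError):
            MlrLDAcp(np.ones(10), led, ranking=ranking)


class TestResults:
    def test_degrees_of_freedom_identity(self, fitted):
        _, res = fitted
        n = len(res.model.endog)
        assert res.df_resid == n - res.delta - 1

    def test_coefficient_table_layout(self, fitted):
        _, res = fitted
        table = res.coefficients_table()
        assert table.iloc[0]["serial"] == "Intercept"
        assert len(table) == res.delta + 1
        assert (table["serial"].iloc[1:].str.startswith("X")).all()

    def test_summary_mentions_key_diagnostics(self, fitted):
        _, res = fitted
        text = res.summary()
        assert f"{res.df_resid} degrees of freedom" in text
        assert "Intercept" in text

    def test_predict_on_training_matches_fitted_values(self, fitted):
        model, res = fitted
        pred = res.predict()
        np.testing.assert_allclose(pred.to_numpy() + res.resid,
                                   model.endog.to_numpy(), rtol=1e-10)

    def test_association_scores_cover_all_candidates(self, fitted):
        model, res = fitted
        scores = res.association_scores()
        assert len(scores) == model.exog.shape[1]
        assert (scores >= 0).all()
        assert (scores[list(res.selected_ids)] > 0).all()


class TestModelSignificance:
    def test_perfect_linear_response_gives_zero_p(self, rng):
        n, C = 40, 6
        led = pd.DataFrame(rng.lognormal(1, 0.5, (n, C)),
                           columns=[f"G{i}" for i in range(C)])
        la = 100.0 + 5.0 * led["G0"]
        p = np.array([1e-15] + [1e-3] * (C - 1))
        res = MlrLDAcp(la, led, p_values=p, config=GammaConfig(D=2)).fit()
        assert model_significance(res) == 0.0

    def test_null_model_p_is_uniform(self, rng):
        # calibration: overall P of a fixed one-predictor fit on pure noise
        # is Uniform(0,1); checked by Kolmogorov-Smirnov over replicates
        from scipy import stats

        n, reps = 100, 300
        pvals = np.empty(reps)
        for i in range(reps):
            led = pd.DataFrame({"G0": rng.normal(size=n)})
            la = rng.normal(loc=10.0, size=n)
            model = MlrLDAcp(la, led, p_values=np.array([0.5]))
            pvals[i] = model.fit_subset([0]).model_p
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
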