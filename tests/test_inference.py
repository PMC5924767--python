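"""ANOVA/Tukey summaries, enumeration, weights, averaging, predictions."""

import numpy as np
import pandas as pd
import pytest

from fintrack.gls import ColumnInfo, FittedModel, ModelSpec, build_design, fit_gls
from fintrack.inference import (
    FailedFit,
    akaike_weights,
    compare_model_sets,
    enumerate_and_fit,
    model_average,
    predict_marginal,
    summarize_individuals,
)


class TestSummarizeIndividuals:
    def test_identical_distributions_give_f_zero_p_one(self):
        vals = np.r_[[1.0, 2, 3], [1.0, 2, 3]]
        ids = np.r_[[0] * 3, [1] * 3]
        s = summarize_individuals(vals, ids)
        assert s.anova_f == pytest.approx(0.0)
        assert s.anova_p == pytest.approx(1.0)
        assert s.tukey["p"].to_numpy() == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # groups (1,2,3) and (11,12,13): SSB = 150 (df 1), SSW = 4 (df 4)
        # -> F = (150/1) / (4/4) = 150
        vals = np.r_[[1.0, 2, 3], [11.0, 12, 13]]
        ids = np.r_[[0] * 3, [1] * 3]
        s = summarize_individuals(vals, ids)
        assert s.anova_f == pytest.approx(150.0)
        assert s.anova_df == (1, 4)
        assert s.anova_p < 0.001

    def test_single_individual_skips_tests(self):
        s = summarize_individuals(np.arange(10.0), np.zeros(10))
        assert s.anova_f is None and s.tukey is None
        assert len(s.means) == 1

    def test_histograms_cover_all_values(self, rng):
        vals = rng.normal(size=200)
        ids = rng.integers(0, 3, 200)
        s = summarize_individuals(vals, ids)
        total = sum(h[0].sum() for h in s.histograms.values())
        assert total == 200


def toy_models():
    """Three hand-specified single-covariate fits for arithmetic checks."""
    cols2 = [ColumnInfo("(Intercept)", "", "intercept"),
             ColumnInfo("v1", "v1", "linear", 0.0, 1.0)]
    cols1 = [ColumnInfo("(Intercept)", "", "intercept")]

    def mk(cols, terms, beta, se, ll, k, n=50):
        beta = np.asarray(beta, float)
        se = np.asarray(se, float)
        from fintrack.gls import compute_aicc
        return FittedModel(
            terms=terms, columns=cols, beta=beta, se=se, cov=np.diag(se**2),
            sigma=1.0, rho=0.0, delta=np.ones(1), group_levels=np.array([0]),
            loglik=ll, n=n, k=k, aicc=compute_aicc(ll, k, n), r2=0.5,
        )

    m1 = mk(cols2, ("v1",), [0.0, 1.0], [0.1, 0.20], -100.0, 3)
    m2 = mk(cols2, ("v1",), [0.0, 2.0], [0.1, 0.30], -101.0, 3)
    m3 = mk(cols1, (), [0.0], [0.1], -108.0, 2)
    return [m1, m2, m3]


class TestAkaikeWeights:
    def test_two_unit_delta_weights(self):
        models = toy_models()[:2]  # equal k: delta AICc = 2.0
        w = akaike_weights(models)
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-4)
        assert w[1] == pytest.approx(np.exp(-1.0) / (1 + np.exp(-1.0)), abs=1e-4)

    def test_normalization_exact(self):
        w = akaike_weights(toy_models())
        assert abs(w.sum() - 1.0) < 1e-12

    def test_small_sample_rejected(self):
        m = toy_models()[0]
        m.aicc = np.inf
        with pytest.raises(ValueError, match="small"):
            akaike_weights([m])

    def test_failed_fits_skipped(self):
        models = toy_models() + [FailedFit(("v9",), "boom")]
        assert len(akaike_weights(models)) == 3


class TestModelAverage:
    def test_weighted_mean_of_conditional_models(self):
        models = toy_models()
        res = model_average(models, np.array([0.75, 0.25, 0.0]))
        row = res.table.set_index("column").loc["v1"]
        assert row["beta"] == pytest.approx(1.25)
        assert row["w_plus"] == pytest.approx(1.0)

    def test_unconditional_se_hand_formula(self):
        models = toy_models()
        w = np.array([0.5, 0.3, 0.2])
        res = model_average(models, w)
        wn = np.array([0.5, 0.3]) / 0.8
        b = np.array([1.0, 2.0])
        s = np.array([0.20, 0.30])
        bbar = float(wn @ b)
        se = float(wn @ np.sqrt(s**2 + (b - bbar) ** 2))
        row = res.table.set_index("column").loc["v1"]
        assert row["beta"] == pytest.approx(bbar, abs=1e-12)
        assert row["se"] == pytest.approx(se, abs=1e-12)
        assert row["ci_low"] == pytest.approx(bbar - 1.96 * se, abs=1e-12)
        assert row["w_plus"] == pytest.approx(0.8, abs=1e-12)

    def test_variable_in_every_model_has_unit_importance(self):
        models = toy_models()[:2]
        res = model_average(models, akaike_weights(models))
        row = res.table.set_index("column").loc["v1"]
        assert row["w_plus"] == pytest.approx(1.0)

    def test_effect_flag_follows_ci(self):
        models = toy_models()
        res = model_average(models, np.array([0.9, 0.1, 0.0]))
        row = res.table.set_index("column").loc["v1"]
        assert row["effect"] == (row["ci_low"] > 0 or row["ci_high"] < 0)


class TestEnumeration:
    def make_table(self, rng, n=150):
        t0 = pd.Timestamp("2020-01-01")
        x = {v: rng.normal(size=n) for v in ("salinity", "bathymetry", "ssh",
                                             "velocity", "hour_of_day")}
        y = 0.2 + 0.5 * x["salinity"] + rng.normal(0, 0.4, n)
        return pd.DataFrame({
            "id": 0, "time": t0 + pd.to_timedelta(np.arange(n), "min"),
            "turning_angle": y, **x,
        })

    def test_five_variables_give_32_models(self, rng):
        tab = self.make_table(rng)
        _, models = enumerate_and_fit(
            tab, ("salinity", "bathymetry", "ssh", "velocity", "hour_of_day"),
            "turning_angle", estimate_rho=False, estimate_delta=False)
        assert len(models) == 32
        assert models[0].terms == ()  # intercept-only model present

    def test_two_variable_aiccs_match_direct_fits(self, rng):
        tab = self.make_table(rng)
        _, models = enumerate_and_fit(tab, ("salinity", "bathymetry"),
                                      "turning_angle",
                                      estimate_rho=False, estimate_delta=False)
        assert len(models) == 4
        for m in models:
            d = build_design(tab, ModelSpec("turning_angle", m.terms))
            direct = fit_gls(d, estimate_rho=False, estimate_delta=False)
            assert m.aicc == pytest.approx(direct.aicc, rel=1e-9)

    def test_loglik_monotone_on_nesting(self, rng):
        tab = self.make_table(rng)
        _, models = enumerate_and_fit(
            tab, ("salinity", "bathymetry", "ssh"), "turning_angle",
            estimate_rho=False, estimate_delta=False)
        by_terms = {frozenset(m.terms): m.loglik for m in models}
        for terms, ll in by_terms.items():
            for other, ll2 in by_terms.items():
                if terms < other:
                    assert ll2 >= ll - 1e-6


class TestCompareModelSets:
    def run_sets(self, rng, couple="bathymetry"):
        n = 200
        t0 = pd.Timestamp("2020-01-01")
        tab = pd.DataFrame({
            "id": 0, "time": t0 + pd.to_timedelta(np.arange(n), "min"),
            **{v: rng.normal(size=n) for v in ("salinity", "bathymetry",
                                               "distance_to_coast")},
        })
        tab["turning_angle"] = 0.6 * tab[couple] + rng.normal(0, 0.3, n)
        out = []
        for vset in (("bathymetry", "salinity"), ("distance_to_coast", "salinity")):
            _, models = enumerate_and_fit(tab, vset, "turning_angle",
                                          estimate_rho=False, estimate_delta=False)
            out.append(model_average(models, akaike_weights(models)))
        return out

    def test_identical_sets_tie_to_a(self, rng):
        a = self.run_sets(rng)[0]
        choice = compare_model_sets(a, a)
        assert choice.selected == "A" and choice.tie and choice.delta_aicc == 0.0

    def test_planted_driver_wins(self, rng):
        a, b = self.run_sets(rng, couple="bathymetry")
        assert compare_model_sets(a, b).selected == "A"
        a2, b2 = self.run_sets(rng, couple="distance_to_coast")
        assert compare_model_sets(a2, b2).selected == "B"

    def test_mismatched_rows_rejected(self, rng):
        a, b = self.run_sets(rng)
        b.n -= 1
        with pytest.raises(ValueError, match="incomparable"):
            compare_model_sets(a, b)


class TestPredictMarginal:
    def test_intercept_only_curve_is_flat(self, rng):
        n = 100
        tab = pd.DataFrame({
            "id": 0,
            "time": pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n), "min"),
            "speed": np.full(n, 0.5) * 10 ** rng.normal(0, 1e-9, n),
            "salinity": rng.normal(33, 1, n),
        })
        design = build_design(tab, ModelSpec("speed", ("salinity",)))
        model = fit_gls(design, estimate_rho=False, estimate_delta=False)
        curve = predict_marginal(design, model, "salinity")
        assert np.allclose(curve["prediction"], 0.5, atol=1e-6)

    def test_negative_effect_curve_decreases(self, rng):
        n = 400
        sal = rng.normal(33, 1.5, n)
        y = -0.2 - 0.08 * sal + rng.normal(0, 0.05, n)
        tab = pd.DataFrame({
            "id": 0,
            "time": pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n), "min"),
            "speed": 10.0**y, "salinity": sal,
        })
        design = build_design(tab, ModelSpec("speed", ("salinity",)))
        model = fit_gls(design, estimate_rho=False, estimate_delta=False)
        curve = predict_marginal(design, model, "salinity")
        assert (np.diff(curve["prediction"]) < 0).all()

    def test_band_narrowest_at_mean(self, rng):
        n = 400
        sal = rng.normal(0, 1, n)
        tab = pd.DataFrame({
            "id": 0,
            "time": pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n), "min"),
            "turning_angle": 50 + 5 * sal + rng.normal(0, 10, n),
            "salinity": sal,
        })
        design = build_design(tab, ModelSpec("turning_angle", ("salinity",)))
        model = fit_gls(design, estimate_rho=False, estimate_delta=False)
        curve = predict_marginal(design, model, "salinity")
        width = curve["upper"] - curve["lower"]
        mid = np.argmin(np.abs(curve["salinity"] - sal.mean()))
        assert width.iloc[mid] <= width.iloc[0]
        assert width.iloc[mid] <= width.iloc[len(width) - 1]

    def test_extrapolation_warns_and_flags(self, rng):
        n = 100
        tab = pd.DataFrame({
            "id": 0,
            "time": pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n), "min"),
            "turning_angle": rng.normal(40, 5, n),
            "salinity": rng.uniform(30, 35, n),
        })
        design = build_design(tab, ModelSpec("turning_angle", ("salinity",)))
        model = fit_gls(design, estimate_rho=False, estimate_delta=False)
        with pytest.warns(UserWarning, match="outside"):
            curve = predict_marginal(design, model, "salinity",
                                     grid=np.array([20.0, 32.0]))
        assert list(curve["extrapolated"]) == [True, False]
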