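"""Price imputation, censoring encoding, AFT fits, averaging, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from labelaudit import censored_standardisation as cs
from labelaudit.adjudication import adjudicate_cohort
from labelaudit.synthetic_data import StudyDesign, generate_products


def perfect_calls(truth):
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "status": "assigned",
            "species": truth["true_species"],
        }
    )



class TestImputePrice:
    def test_identity_when_complete(self, cohort):
        products, _ = cohort
        full = products.copy()
        full["price_per_kg"] = full["price_per_kg"].fillna(10.0)
        out = cs.impute_price(full, seed=0)
        pd.testing.assert_frame_equal(out, full)

    def test_forced_nearest_donor(self):
        # one covariate pattern per row; missing row shares pattern with donor 'a'
        df = pd.DataFrame(
            {
                "seafood_group": ["a"] * 6 + ["b"] * 6 + ["a"],
                "outlet_type": ["x"] * 13,
                "origin": ["d"] * 13,
                "price_per_kg": [10.0] * 6 + [100.0] * 6 + [np.nan],
            }
        )
        out = cs.impute_price(df, k_donors=1, seed=0)
        assert out.loc[12, "price_per_kg"] == 10.0

    def test_imputed_values_within_observed_support(self, cohort):
        products, _ = cohort
        out = cs.impute_price(products, seed=3)
        observed = set(products["price_per_kg"].dropna())
        imputed = out.loc[products["price_per_kg"].isna(), "price_per_kg"]
        assert set(imputed) <= observed
        # MCAR missingness: imputed distribution close to observed (KS < 0.2)
        ks = stats.ks_2samp(sorted(observed), imputed).statistic
        assert ks < 0.2

    def test_all_missing_raises(self):
        df = pd.DataFrame(
            {"seafood_group": ["a"] * 12, "outlet_type": "x", "origin": "d",
             "price_per_kg": [np.nan] * 12}
        )
        with pytest.raises(ValueError):
            cs.impute_price(df)


class TestEncode:
    def test_examples_and_roundtrip(self, adjudicated):
        obs, n_excl = cs.encode_censoring(adjudicated)
        assert len(obs) + n_excl == len(adjudicated)
        # species-level correct product -> censored at 4
        sp_correct = adjudicated[
            (adjudicated["specificity"] == 4)
            & (adjudicated["status_comprehensive"] == "correct")
        ]["sample_id"]
        sub = obs[obs["sample_id"].isin(sp_correct)]
        assert (sub["level"] == 4).all() and (~sub["event"]).all()
        # family-level mislabelled product -> event at 2
        fam_wrong = adjudicated[
            (adjudicated["specificity"] == 2)
            & (adjudicated["status_comprehensive"] == "mislabelled")
        ]["sample_id"]
        sub = obs[obs["sample_id"].isin(fam_wrong)]
        assert (sub["level"] == 2).all() and sub["event"].all()

        decoded = cs.decode_censoring(obs)
        merged = decoded.merge(
            adjudicated[["sample_id", "specificity", "status_comprehensive"]],
            on="sample_id",
            suffixes=("_dec", ""),
        )
        assert (merged["specificity_dec"] == merged["specificity"]).all()
        assert (
            merged["status_comprehensive_dec"] == merged["status_comprehensive"]
        ).all()

    def test_level_times_spacing_configurable(self, adjudicated):
        obs, _ = cs.encode_censoring(adjudicated, level_times={1: 0.5, 2: 1, 3: 2, 4: 8})
        assert set(obs["time"]) <= {0.5, 1.0, 2.0, 8.0}


def simulate_weibull_aft(n, beta, rho, seed, censor_at=4.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    lam = np.exp(beta[0] + beta[1] * x)
    t = lam * rng.weibull(rho, size=n)
    event = t <= censor_at
    return pd.DataFrame(
        {
            "sample_id": range(n),
            "level": 4,
            "time": np.minimum(t, censor_at),
            "event": event,
            "x": x,
        }
    )


class TestFit:
    def test_no_events_refuses(self):
        obs = pd.DataFrame(
            {"sample_id": [1, 2], "level": [4, 4], "time": [4.0, 4.0], "event": [False, False]}
        )
        with pytest.raises(ValueError):
            cs.fit_censored_model(obs)

    def test_all_events_at_level_one_drives_survival_to_zero(self):
        obs = pd.DataFrame(
            {
                "sample_id": range(40),
                "level": [1] * 40,
                "time": [1.0] * 40,
                "event": [True] * 40,
            }
        )
        fit = cs.fit_censored_model(obs, ())
        s4 = cs._survival(fit.distribution, np.array([4.0]), np.array([fit.params["Intercept"]]), fit.shape)
        assert s4.item() < 0.05

    def test_weibull_parameter_recovery(self):
        """Estimates within 3 SE of truth on data simulated from the model."""
        beta, rho = (0.9, 0.5), 1.4
        obs = simulate_weibull_aft(5000, beta, rho, seed=21)
        fit = cs.fit_censored_model(obs, ("x",), "weibull", event_likelihood="exact")
        se_x = np.sqrt(fit.cov.loc["x", "x"])
        se_i = np.sqrt(fit.cov.loc["Intercept", "Intercept"])
        assert abs(fit.params["x"] - beta[1]) < 3 * se_x
        assert abs(fit.params["Intercept"] - beta[0]) < 3 * se_i
        assert abs(fit.shape - rho) < 0.1

    def test_aic_definition(self):
        obs = simulate_weibull_aft(300, (0.5, 0.3), 1.2, seed=3)
        fit = cs.fit_censored_model(obs, ("x",))
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)


class TestAveraging:
    def test_akaike_weight_identities(self):
        assert cs.akaike_weights([100.0]) == pytest.approx([1.0])
        assert cs.akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
        # invariant to adding a constant to all log-likelihoods (AIC shift)
        a = cs.akaike_weights([3.0, 5.0, 9.0])
        b = cs.akaike_weights([103.0, 105.0, 109.0])
        assert np.allclose(a, b)

    def test_single_candidate_average_is_identity(self):
        obs = simulate_weibull_aft(400, (0.8, 0.0), 1.0, seed=5)
        model = cs.select_and_average(obs, ())
        assert len(model.candidates) == 1
        assert model.weights == pytest.approx([1.0])
        pd.testing.assert_series_equal(
            model.averaged_coef, model.candidates[0].params, check_names=False
        )

    def test_true_driver_outranks_null_terms(self):
        """A covariate that truly shifts the hazard gets higher importance
        than pure-noise covariates, across seeds."""
        wins = 0
        for seed in range(8):
            obs = simulate_weibull_aft(800, (0.7, 0.8), 1.3, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            obs["noise1"] = rng.normal(size=len(obs))
            obs["noise2"] = rng.choice(["u", "v"], size=len(obs))
            model = cs.select_and_average(obs, ("x", "noise1", "noise2"), event_likelihood="exact")
            if model.importance["x"] > max(model.importance["noise1"], model.importance["noise2"]):
                wins += 1
        assert wins >= 7

    def test_confidence_set_cumulative_weight(self):
        obs = simulate_weibull_aft(500, (0.8, 0.4), 1.2, seed=9)
        obs["noise"] = np.random.default_rng(2).normal(size=len(obs))
        model = cs.select_and_average(obs, ("x", "noise"))
        kept_w = model.aic_table.loc[model.aic_table["in_confidence_set"], "weight"]
        assert kept_w.sum() >= 0.95 - 1e-9


class TestPredictIncidence:
    def test_flat_hazard_null_model_recovers_closed_form(self):
        """Constant-hazard latent mislabelling: the null fit's curve matches
        the exponential cumulative incidence 1 - exp(-lam*l) at every level."""
        rng = np.random.default_rng(31)
        n = 4000
        lam = -np.log(1 - 0.3) / 4  # F(4) = 30%
        t_latent = rng.exponential(1 / lam, size=n)
        level = rng.choice([1, 2, 3, 4], size=n)
        event = t_latent <= level  # mismatch known only up to the label level
        obs = pd.DataFrame(
            {"sample_id": range(n), "level": level, "time": level.astype(float), "event": event}
        )
        model = cs.select_and_average(obs, ())
        curve = cs.predict_incidence(model, obs)
        for _, row in curve.iterrows():
            truth = 100 * (1 - np.exp(-lam * row["level"]))
            assert abs(row["predicted"] - truth) < 3.0

    def test_monotone_and_bracketing(self, adjudicated):
        obs, _ = cs.encode_censoring(adjudicated)
        model = cs.select_and_average(obs, ("seafood_group",))
        curve = cs.predict_incidence(model, obs)
        assert (np.diff(curve["predicted"]) >= -1e-9).all()
        assert (curve["ci_low"] <= curve["predicted"] + 1e-9).all()
        assert (curve["predicted"] <= curve["ci_high"] + 1e-9).all()

    def test_predicted_species_level_exceeds_observed_overall(self, adjudicated):
        obs, _ = cs.encode_censoring(adjudicated)
        model = cs.select_and_average(obs, ())
        curve = cs.predict_incidence(model, obs)
        observed_overall = 100.0 * obs["event"].mean()
        predicted_sp = curve.loc[curve["level"] == 4, "predicted"].iloc[0]
        assert predicted_sp >= observed_overall - 1e-9

    def test_standardise_gives_single_profile_curve(self, adjudicated):
        obs, _ = cs.encode_censoring(adjudicated)
        model = cs.select_and_average(obs, ("origin",))
        c = cs.predict_incidence(model, obs, standardise=True)
        assert len(c) == 4 and c["predicted"].notna().all()


class TestOrdinal:
    def test_intercept_only_reproduces_marginals(self, cohort):
        products, _ = cohort
        from labelaudit.synthetic_data import demo_reference

        ref = demo_reference()
        products = products.copy()
        products["specificity"] = [
            ref.label_specificity(t) for t in products["label_max_detail"]
        ]
        fit = cs.fit_ordinal_specificity_single(products, ())
        # thresholds imply cumulative probabilities equal to marginal freqs
        thresholds = fit.params.values
        cum = 1 / (1 + np.exp(-np.cumsum(np.r_[thresholds[0], np.exp(thresholds[1:])])))
        emp = np.cumsum(
            products["specificity"].value_counts(normalize=True).sort_index().values
        )[:-1]
        # statsmodels parameterises increments on the log scale
        cum2 = 1 / (1 + np.exp(-(np.r_[thresholds[0], thresholds[0] + np.cumsum(np.exp(thresholds[1:]))])))
        assert np.allclose(cum2, emp, atol=0.01)

    def test_known_effect_sign_recovered(self):
        """A group that truly lowers specificity is detected with the right
        sign in most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1500
            grp = rng.choice(["a", "b"], size=n)
            eta = np.where(grp == "b", 1.5, 0.0) + rng.logistic(size=n)
            spec = np.digitize(eta, [-1, 0.5, 2.0]) + 1
            df = pd.DataFrame({"specificity": spec, "grp": grp})
            fit = cs.fit_ordinal_specificity_single(df, ("grp",))
            coef = fit.params[[i for i in fit.params.index if "grp" in i][0]]
            if fit.converged and coef > 0:
                hits += 1
        assert hits >= 9

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "specificity": [1] * 30 + [4] * 30,
                "grp": ["a"] * 30 + ["b"] * 30,
            }
        )
        fit = cs.fit_ordinal_specificity_single(df, ("grp",))
        assert fit.flagged_separation or not fit.converged

    def test_explained_deviance_reported(self, cohort):
        products, _ = cohort
        from labelaudit.synthetic_data import demo_reference

        ref = demo_reference()
        products = products.copy()
        products["specificity"] = [
            ref.label_specificity(t) for t in products["label_max_detail"]
        ]
        products = cs.impute_price(products, seed=1)
        fit = cs.fit_ordinal_specificity_single(products, ("outlet_type", "price_per_kg"))
        assert 0.0 <= fit.explained_deviance < 1.0
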