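"""Baseline/genetic fitting, LASSO selection, prediction and calibration."""

import numpy as np
import pandas as pd
import pytest

from multiprs import ensemble as ens
from multiprs import evaluate as ev
from multiprs.cohort import split_train_test
from multiprs.prs import FeatureTable


def _cohort(n, seed=0, groups=("White", "Black")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "age": rng.uniform(30, 80, n),
        "sex": rng.choice(["female", "male"], n),
        "group": rng.choice(list(groups), n),
        "study": rng.choice(["s1", "s2", "s3"], n),
        "bmi": rng.normal(28, 5, n),
        "med_use": False,
    })


def _features(values: np.ndarray, ids) -> FeatureTable:
    names = [f"prs{k}" for k in range(values.shape[1])]
    return FeatureTable(
        pd.DataFrame(values, columns=names,
                     index=pd.Index([str(i) for i in ids], name="individual_id")),
        pd.DataFrame([
            {"name": nm, "source_id": "sim", "p_threshold": 0.01,
             "region_id": f"r{k}", "n_variants_used": 1}
            for k, nm in enumerate(names)
        ]),
    )


class TestFitBaselineLinear:
    def test_noiseless_linear_recovery_pve_100(self):
        cohort = _cohort(2000, seed=1)
        cohort["sbp"] = 100 + 0.5 * cohort["age"] + 0.8 * cohort["bmi"]
        train, test = split_train_test(cohort, 0.7, seed=2)
        model = ens.fit_baseline(train, "sbp", engine="linear")
        pred = model.predict(test)
        assert ev.pve(test["sbp"], pred) == pytest.approx(100.0, abs=0.1)

    def test_missing_phenotype_column_raises(self):
        with pytest.raises(ValueError, match="phenotype"):
            ens.fit_baseline(_cohort(50), "sbp", engine="linear")

    def test_single_level_covariate_warns(self):
        cohort = _cohort(200, seed=3, groups=("White",))
        cohort["sbp"] = 120 + 0.1 * cohort["age"]
        with pytest.warns(UserWarning, match="single level"):
            ens.fit_baseline(cohort, "sbp", engine="linear")

    def test_unseen_category_level_named_in_error(self):
        cohort = _cohort(300, seed=4)
        cohort["sbp"] = 120.0 + np.random.default_rng(4).normal(0, 5, 300)
        model = ens.fit_baseline(cohort, "sbp", engine="linear")
        new = cohort.copy()
        new.loc[0, "group"] = "Martian"
        with pytest.raises(ValueError, match="Martian"):
            model.predict(new)


class TestResiduals:
    def test_elementwise_difference(self):
        cohort = _cohort(100, seed=5)
        cohort["sbp"] = 130.0
        model = ens.fit_baseline(cohort, "sbp", engine="linear")
        res = ens.compute_residuals(model, cohort.assign(sbp=140.0))
        assert res == pytest.approx(np.full(100, 10.0), abs=1e-8)

    def test_training_mean_zero_for_ols(self):
        cohort = _cohort(500, seed=6)
        rng = np.random.default_rng(6)
        cohort["sbp"] = 120 + 0.4 * cohort["age"] + rng.normal(0, 10, 500)
        model = ens.fit_baseline(cohort, "sbp", engine="linear")
        assert ens.compute_residuals(model, cohort).mean() == pytest.approx(0.0, abs=1e-8)


class TestFitGenetic:
    def test_noiseless_prs_coefficient_recovery(self):
        cohort = _cohort(1000, seed=7)
        rng = np.random.default_rng(7)
        F = rng.normal(0, 2, size=(1000, 3))
        feats = _features(F, cohort["individual_id"])
        resid = 1.7 * F[:, 0]
        model = ens.fit_genetic(cohort, resid, feats, engine="linear")
        coefs = model.engine.coefficients().set_index("name")["coef"]
        assert coefs["prs0"] == pytest.approx(1.7, abs=1e-6)
        pred = model.predict(cohort, feats)
        assert ev.pve(resid, pred) == pytest.approx(100.0, abs=1e-6)

    def test_study_excluded_from_xg(self):
        cohort = _cohort(100, seed=8)
        feats = _features(np.zeros((100, 2)), cohort["individual_id"])
        with pytest.raises(ValueError, match="study"):
            ens.fit_genetic(cohort, np.zeros(100), feats, engine="linear",
                            covariates=("age", "study"))

    def test_misaligned_features_raise(self):
        cohort = _cohort(100, seed=9)
        feats = _features(np.zeros((60, 2)), [f"i{k}" for k in range(60)])
        with pytest.raises(ValueError, match="misaligned"):
            ens.fit_genetic(cohort, np.zeros(100), feats, engine="linear")

    def test_missing_prs_column_named_at_prediction(self):
        cohort = _cohort(200, seed=10)
        rng = np.random.default_rng(10)
        feats = _features(rng.normal(size=(200, 2)), cohort["individual_id"])
        model = ens.fit_genetic(cohort, rng.normal(size=200), feats, engine="linear")
        partial = FeatureTable(feats.scores[["prs0"]], feats.meta.iloc[:1])
        with pytest.raises(ValueError, match="prs1"):
            model.predict(cohort, partial)


class TestSelectLocalLasso:
    def test_support_recovery_single_instance(self):
        rng = np.random.default_rng(11)
        n, p = 2000, 50
        X = rng.normal(0, 1, size=(n, p))
        resid = X[:, 3] * 2 + X[:, 17] * 1.5 + X[:, 42] * 1.8 + rng.normal(0, 2, n)
        feats = _features(X, [f"i{k}" for k in range(n)])
        selected, model = ens.select_local_lasso(resid, feats, seed=12)
        assert {"prs3", "prs17", "prs42"} <= set(selected.columns)

    def test_lambda_max_gives_empty_model(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(12)
        X = rng.normal(size=(500, 20))
        y = X[:, 0] + rng.normal(size=500)
        feats = _features(X, [f"i{k}" for k in range(500)])
        _, model = ens.select_local_lasso(y, feats, seed=13)
        lam_max = model.tuning["lambda_max"]
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        boundary = Lasso(alpha=lam_max * (1 + 1e-10)).fit(Xs, y)
        assert np.all(boundary.coef_ == 0)

    def test_null_selects_few_columns_on_average(self):
        counts = []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(400, 30))
            y = rng.normal(size=400)
            feats = _features(X, [f"i{k}" for k in range(400)])
            selected, _ = ens.select_local_lasso(y, feats, seed=rep)
            counts.append(len(selected.columns))
        assert np.mean(counts) <= 2.0

    def test_too_few_columns_rejected(self):
        feats = _features(np.zeros((50, 1)), [f"i{k}" for k in range(50)])
        with pytest.raises(ValueError, match="two"):
            ens.select_local_lasso(np.zeros(50), feats)


class TestEnsemblePrediction:
    def _fitted(self, n=600, seed=14):
        cohort = _cohort(n, seed=seed)
        rng = np.random.default_rng(seed)
        F = rng.normal(size=(n, 2))
        cohort["sbp"] = (120 + 0.4 * cohort["age"] + 2.0 * F[:, 0]
                         + rng.normal(0, 8, n))
        feats = _features(F, cohort["individual_id"])
        baseline = ens.fit_baseline(cohort, "sbp", engine="linear")
        resid = ens.compute_residuals(baseline, cohort)
        genetic = ens.fit_genetic(cohort, resid, feats, engine="linear")
        genetic.phenotype = "sbp"
        return ens.EnsembleModel(baseline, genetic), cohort, feats

    def test_sum_of_components(self):
        model, cohort, feats = self._fitted()
        total = ens.predict_ensemble(model, cohort, feats)
        np.testing.assert_allclose(
            total,
            model.baseline.predict(cohort) + model.genetic.predict(cohort, feats),
        )

    def test_decomposition_identity(self):
        model, cohort, feats = self._fitted()
        d = ens.decompose(model, cohort, feats)
        np.testing.assert_allclose(
            d["y"], d["y_hat_b"] + d["r_hat_b"] + d["r_g"], atol=1e-9
        )
        np.testing.assert_allclose(
            d["y"] - d["y_hat_ensemble"], d["r_g"], atol=1e-9
        )

    def test_zero_genetic_model_reduces_to_baseline(self):
        model, cohort, feats = self._fitted()
        model.genetic.engine.params_ = np.zeros_like(model.genetic.engine.params_)
        np.testing.assert_allclose(
            ens.predict_ensemble(model, cohort, feats),
            model.baseline.predict(cohort),
        )

    def test_bundle_round_trip(self, tmp_path):
        model, cohort, feats = self._fitted()
        path = tmp_path / "m.bundle.json"
        ens.save_bundle(model, path)
        back = ens.load_bundle(path)
        np.testing.assert_allclose(
            ens.predict_ensemble(back, cohort, feats),
            ens.predict_ensemble(model, cohort, feats),
        )
        assert back.genetic.state_hash() == model.genetic.state_hash()


class TestCalibration:
    def test_genetic_model_unchanged(self):
        cohort = _cohort(300, seed=15)
        rng = np.random.default_rng(15)
        F = rng.normal(size=(300, 2))
        cohort["sbp"] = 120 + rng.normal(0, 10, 300)
        feats = _features(F, cohort["individual_id"])
        baseline = ens.fit_baseline(cohort, "sbp", engine="linear")
        resid = ens.compute_residuals(baseline, cohort)
        genetic = ens.fit_genetic(cohort, resid, feats, engine="linear")
        before = genetic.state_hash()
        new_cohort = _cohort(250, seed=16)
        new_cohort["sbp"] = 130 + np.random.default_rng(16).normal(0, 10, 250)
        calibrated = ens.calibrate_to_dataset(new_cohort, genetic, engine="linear",
                                              phenotype="sbp")
        assert calibrated.genetic.state_hash() == before
        assert calibrated.provenance["calibrated"]

    def test_no_shift_preserves_genetic_pve(self):
        # same generative process in both datasets: refitting the baseline
        # should leave the genetic residual PVE essentially unchanged
        def make(seed):
            cohort = _cohort(2000, seed=seed)
            rng = np.random.default_rng(seed)
            F = rng.normal(size=(2000, 2))
            cohort["sbp"] = (120 + 0.4 * cohort["age"] + 3.0 * F[:, 0]
                             + rng.normal(0, 8, 2000))
            return cohort, _features(F, cohort["individual_id"])

        cohort_a, feats_a = make(17)
        cohort_b, feats_b = make(18)
        baseline = ens.fit_baseline(cohort_a, "sbp", engine="linear")
        resid = ens.compute_residuals(baseline, cohort_a)
        genetic = ens.fit_genetic(cohort_a, resid, feats_a, engine="linear")
        genetic.phenotype = "sbp"

        original = ens.EnsembleModel(baseline, genetic)
        calibrated = ens.calibrate_to_dataset(cohort_b, genetic, engine="linear",
                                              phenotype="sbp")
        def g_pve(model, cohort, feats):
            r_b = cohort["sbp"] - model.baseline.predict(cohort)
            return ev.pve(r_b, model.genetic.predict(cohort, feats))

        assert g_pve(calibrated, cohort_b, feats_b) == pytest.approx(
            g_pve(original, cohort_b, feats_b), abs=2.0
        )


class TestGbtEngine:
    def test_seed_determinism(self):
        cohort = _cohort(400, seed=19)
        rng = np.random.default_rng(19)
        cohort["sbp"] = 120 + 0.5 * cohort["age"] + rng.normal(0, 8, 400)
        m1 = ens.fit_baseline(cohort, "sbp", engine="gbt", seed=3, n_trials=2,
                              cv_folds=3)
        m2 = ens.fit_baseline(cohort, "sbp", engine="gbt", seed=3, n_trials=2,
                              cv_folds=3)
        np.testing.assert_array_equal(m1.predict(cohort), m2.predict(cohort))
        assert m1.tuning["chosen"] == m2.tuning["chosen"]

    def test_null_phenotype_small_heldout_pve(self):
        rng = np.random.default_rng(20)
        cohort = _cohort(1500, seed=20)
        cohort["sbp"] = 120 + rng.normal(0, 10, 1500)
        train, test = split_train_test(cohort, 0.7, seed=21)
        model = ens.fit_baseline(train, "sbp", engine="gbt", seed=4, n_trials=2,
                                 cv_folds=3)
        assert -5.0 <= ev.pve(test["sbp"], model.predict(test)) <= 5.0

    def test_interaction_favors_gbt_over_linear(self):
        rng = np.random.default_rng(22)
        n = 3000
        cohort = _cohort(n, seed=22)
        inter = 0.12 * (cohort["age"] - 55) * (cohort["bmi"] - 28)
        cohort["sbp"] = 120 + 0.3 * cohort["age"] + inter + rng.normal(0, 8, n)
        train, test = split_train_test(cohort, 0.7, seed=23)
        linear = ens.fit_baseline(train, "sbp", engine="linear")
        gbt = ens.fit_baseline(train, "sbp", engine="gbt", seed=5, n_trials=0,
                               cv_folds=3)
        pve_lin = ev.pve(test["sbp"], linear.predict(test), residual_based=True)
        pve_gbt = ev.pve(test["sbp"], gbt.predict(test), residual_based=True)
        assert pve_gbt > pve_lin
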