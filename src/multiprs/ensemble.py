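"""Two-stage baseline + genetic ensemble for blood-pressure prediction.

The ensemble consists of two consecutively trained components:

* a **baseline model** M_b predicting the phenotype from non-genetic
  covariates x_b (age, sex, group, BMI, study), yhat_b = M_b(x_b);
* a **genetic model** M_g predicting the baseline residuals
  r_b = y - yhat_b from the transferable covariates x_g (x_b minus the
  dataset-specific ``study``) and a set of PRS features g,
  rhat_b = M_g(x_g, g).

The ensemble prediction is yhat_ensemble = yhat_b + rhat_b, and the observed
phenotype decomposes exactly as y = yhat_b + rhat_b + r_g with r_g the
genetic model's residual.  Splitting the model this way lets the baseline be
refit (calibrated) on a new dataset while the genetic component — trained on
features harmonizable across datasets — is reused unchanged.

Engines: ordinary least squares with one-hot categories (``linear``),
gradient-boosted trees via xgboost with seeded random-search CV tuning
(``gbt``), and an L1-penalised linear model used by the local-PRS selection
stage (``lasso``).
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import child_rng, child_seed
from .prs import FeatureTable

logger = logging.getLogger(__name__)

BASELINE_COVARIATES = ("age", "sex", "group", "bmi", "study")
#: study is dataset-specific and excluded from the transferable genetic model.
GENETIC_COVARIATES = ("age", "sex", "group", "bmi")

#: Random-search space for gradient-boosted trees (tree count governed by
#: early stopping up to the cap).
GBT_SEARCH_SPACE = {
    "max_depth": (2, 8),
    "learning_rate": (0.01, 0.3),
    "subsample": (0.5, 1.0),
    "colsample_bytree": (0.5, 1.0),
}
GBT_MAX_TREES = 2000
GBT_EARLY_STOPPING = 25
GBT_DEFAULT_PARAMS = {
    "max_depth": 3, "learning_rate": 0.1, "subsample": 1.0, "colsample_bytree": 1.0
}
DEFAULT_N_TRIALS = 20


# ----------------------------------------------------------------- design

class Design:
    """Covariate/feature design matrix with recorded category levels.

    Non-numeric columns are one-hot encoded (first level dropped).  Unseen
    category levels at prediction time raise ``ValueError`` naming the level
    — never silent coercion.
    """

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        self.levels_: dict[str, list] = {}
        self.output_names_: list[str] = []

    def fit(self, df: pd.DataFrame) -> "Design":
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {', '.join(missing)}")
        self.levels_ = {}
        self.output_names_ = []
        for c in self.columns:
            if pd.api.types.is_numeric_dtype(df[c]) and df[c].dtype != bool:
                self.output_names_.append(c)
            else:
                levels = sorted(df[c].astype(str).unique())
                if len(levels) == 1:
                    warnings.warn(
                        f"covariate {c!r} has a single level ({levels[0]!r}); "
                        "dropped from the encoding"
                    )
                self.levels_[c] = levels
                self.output_names_.extend(f"{c}[{l}]" for l in levels[1:])
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.columns:
            if c not in df.columns:
                raise ValueError(f"missing covariate column: {c}")
            if c in self.levels_:
                vals = df[c].astype(str)
                unseen = set(vals.unique()) - set(self.levels_[c])
                if unseen:
                    raise ValueError(
                        f"unseen category level(s) {sorted(unseen)} in column {c!r}"
                    )
                for l in self.levels_[c][1:]:
                    cols.append((vals == l).to_numpy(dtype=float))
            else:
                cols.append(df[c].to_numpy(dtype=float))
        if not cols:
            return np.empty((len(df), 0))
        return np.column_stack(cols)


# ----------------------------------------------------------------- engines

class LinearEngine:
    """OLS with intercept via statsmodels; keeps coefficient SEs."""

    name = "linear"

    def __init__(self):
        self.params_ = None
        self.bse_ = None
        self.names_ = None

    def fit(self, X: np.ndarray, y: np.ndarray, names, seed=0, **_):
        import statsmodels.api as sm

        Xc = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, Xc).fit()
        self.params_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.names_ = ["const"] + list(names)
        return {"engine": self.name, "n_params": len(self.params_)}

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.params_[0] + X @ self.params_[1:]

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names_, "coef": self.params_, "se": self.bse_})

    def payload(self) -> dict:
        return {
            "params": self.params_.tolist(),
            "bse": self.bse_.tolist(),
            "names": self.names_,
        }

    @classmethod
    def from_payload(cls, payload):
        eng = cls()
        eng.params_ = np.array(payload["params"])
        eng.bse_ = np.array(payload["bse"])
        eng.names_ = payload["names"]
        return eng


class GBTEngine:
    """Gradient-boosted trees (xgboost) with seeded random-search CV tuning.

    Each trial samples hyperparameters from ``GBT_SEARCH_SPACE``; K-fold CV
    with early stopping scores the trial by mean validation PVE (residual
    form, i.e. R^2-style) and records the mean stopped tree count; the best
    trial is refit on the full training data at that tree count.
    ``n_trials=0`` skips the search and uses ``GBT_DEFAULT_PARAMS`` (tree
    count still chosen by CV early stopping).
    """

    name = "gbt"

    def __init__(self):
        self.booster_ = None
        self.params_ = None

    @staticmethod
    def _sample_params(rng) -> dict:
        lo, hi = GBT_SEARCH_SPACE["max_depth"]
        return {
            "max_depth": int(rng.integers(lo, hi + 1)),
            "learning_rate": float(np.exp(rng.uniform(
                np.log(GBT_SEARCH_SPACE["learning_rate"][0]),
                np.log(GBT_SEARCH_SPACE["learning_rate"][1]),
            ))),
            "subsample": float(rng.uniform(*GBT_SEARCH_SPACE["subsample"])),
            "colsample_bytree": float(rng.uniform(*GBT_SEARCH_SPACE["colsample_bytree"])),
        }

    def _cv_score(self, params, X, y, cv_folds, seed):
        import xgboost as xgb
        from sklearn.model_selection import KFold

        scores, best_iters = [], []
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % 2**31)
        for tr, va in kf.split(X):
            model = xgb.XGBRegressor(
                n_estimators=GBT_MAX_TREES,
                early_stopping_rounds=GBT_EARLY_STOPPING,
                random_state=seed % 2**31, n_jobs=1, tree_method="hist",
                verbosity=0, **params,
            )
            model.fit(X[tr], y[tr], eval_set=[(X[va], y[va])], verbose=False)
            pred = model.predict(X[va])
            var = np.var(y[va], ddof=1)
            score = 1.0 - np.var(y[va] - pred, ddof=1) / var if var > 0 else 0.0
            scores.append(float(score))
            best_iters.append(int(model.best_iteration) + 1)
        return float(np.mean(scores)), int(round(np.mean(best_iters)))

    def fit(self, X, y, names, seed=0, cv_folds=5, n_trials=DEFAULT_N_TRIALS, **_):
        import xgboost as xgb

        rng = child_rng(seed, "gbt-tuning")
        trials = []
        candidates = (
            [dict(GBT_DEFAULT_PARAMS)] if n_trials == 0
            else [self._sample_params(rng) for _ in range(n_trials)]
        )
        for params in candidates:
            score, n_trees = self._cv_score(params, X, y, cv_folds, seed)
            trials.append({"params": params, "cv_pve": score * 100.0, "n_trees": n_trees})
        best = max(trials, key=lambda t: t["cv_pve"])
        n_trees = max(best["n_trees"], 1)
        final = xgb.XGBRegressor(
            n_estimators=n_trees, random_state=seed % 2**31, n_jobs=1,
            tree_method="hist", verbosity=0, **best["params"],
        )
        final.fit(X, y, verbose=False)
        self.booster_ = final.get_booster()
        self.params_ = {**best["params"], "n_estimators": n_trees}
        return {
            "engine": self.name, "chosen": self.params_,
            "cv_pve": best["cv_pve"], "trials": trials,
        }

    def predict(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        return self.booster_.predict(xgb.DMatrix(np.asarray(X, dtype=float)))

    def payload(self) -> dict:
        raw = self.booster_.save_raw(raw_format="json")
        return {
            "booster_json_b64": base64.b64encode(bytes(raw)).decode("ascii"),
            "params": self.params_,
        }

    @classmethod
    def from_payload(cls, payload):
        import xgboost as xgb

        eng = cls()
        booster = xgb.Booster()
        booster.load_model(bytearray(base64.b64decode(payload["booster_json_b64"])))
        eng.booster_ = booster
        eng.params_ = payload["params"]
        return eng


class LassoEngine:
    """Standardise-then-LASSO linear model carrying its own scaler state."""

    name = "lasso"

    def __init__(self):
        self.mean_ = None
        self.scale_ = None
        self.coef_ = None
        self.intercept_ = None
        self.alpha_ = None

    def fit(self, X, y, names, seed=0, cv_folds=5, **_):
        from sklearn.linear_model import LassoCV

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        yc = y - y.mean()
        lam_max = np.max(np.abs(Xs.T @ yc)) / len(y)
        alphas = np.geomspace(lam_max, lam_max * 1e-4, 100)
        cv = LassoCV(
            alphas=alphas, cv=cv_folds, random_state=seed % 2**31, max_iter=50000
        )
        cv.fit(Xs, y)
        self.coef_ = cv.coef_
        self.intercept_ = float(cv.intercept_)
        self.alpha_ = float(cv.alpha_)
        return {
            "engine": self.name, "alpha": self.alpha_, "lambda_max": float(lam_max),
            "n_selected": int(np.sum(cv.coef_ != 0)),
        }

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept_ + ((X - self.mean_) / self.scale_) @ self.coef_

    def payload(self) -> dict:
        return {
            "mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
            "coef": self.coef_.tolist(), "intercept": self.intercept_,
            "alpha": self.alpha_,
        }

    @classmethod
    def from_payload(cls, payload):
        eng = cls()
        eng.mean_ = np.array(payload["mean"])
        eng.scale_ = np.array(payload["scale"])
        eng.coef_ = np.array(payload["coef"])
        eng.intercept_ = payload["intercept"]
        eng.alpha_ = payload["alpha"]
        return eng


_ENGINES = {"linear": LinearEngine, "gbt": GBTEngine, "lasso": LassoEngine}


# ------------------------------------------------------------------ models

@dataclass
class BaselineModel:
    """Covariate-only component M_b: yhat_b = M_b(x_b)."""

    engine_name: str
    phenotype: str
    covariates: list[str]
    design: Design
    engine: object
    tuning: dict = field(default_factory=dict)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.engine.predict(self.design.transform(cohort)), dtype=float)


@dataclass
class GeneticModel:
    """Residual component M_g: rhat_b = M_g(x_g, g); excludes ``study``."""

    engine_name: str
    phenotype: str
    covariates: list[str]
    feature_meta: pd.DataFrame
    design: Design
    engine: object
    tuning: dict = field(default_factory=dict)

    def _matrix(self, cohort: pd.DataFrame, features: FeatureTable | None) -> np.ndarray:
        expected = list(self.feature_meta["name"]) if len(self.feature_meta) else []
        if expected:
            if features is None:
                raise ValueError("genetic model requires a PRS feature table")
            missing = [c for c in expected if c not in features.scores.columns]
            if missing:
                raise ValueError(
                    "feature table is missing PRS column(s): "
                    + ", ".join(missing[:5])
                    + (f" (+{len(missing)-5} more)" if len(missing) > 5 else "")
                )
            if len(features.scores) != len(cohort):
                raise ValueError("feature table and cohort are misaligned")
            F = features.scores[expected].to_numpy(dtype=float)
        else:
            F = np.empty((len(cohort), 0))
        X = self.design.transform(cohort) if self.covariates else np.empty((len(cohort), 0))
        return np.column_stack([X, F]) if X.size or F.size else np.empty((len(cohort), 0))

    def predict(self, cohort: pd.DataFrame, features: FeatureTable | None) -> np.ndarray:
        return np.asarray(self.engine.predict(self._matrix(cohort, features)), dtype=float)

    def state_hash(self) -> str:
        payload = json.dumps(self.engine.payload(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class EnsembleModel:
    """Trained baseline + genetic pair; yhat_ensemble = yhat_b + rhat_b."""

    baseline: BaselineModel
    genetic: GeneticModel
    provenance: dict = field(default_factory=dict)


# -------------------------------------------------------------- operations

def _usable(train: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    if phenotype not in train.columns:
        raise ValueError(f"phenotype column {phenotype!r} absent from cohort table")
    return train[train[phenotype].notna()].reset_index(drop=True)


def fit_baseline(
    train: pd.DataFrame,
    phenotype: str,
    engine: str = "gbt",
    cv_folds: int = 5,
    seed: int = 0,
    covariates=BASELINE_COVARIATES,
    n_trials: int = DEFAULT_N_TRIALS,
) -> BaselineModel:
    """Fit M_b on covariates only; gbt hyperparameters tuned by K-fold CV."""
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    train = _usable(train, phenotype)
    design = Design(list(covariates)).fit(train)
    X = design.transform(train)
    y = train[phenotype].to_numpy(dtype=float)
    eng = _ENGINES[engine]()
    tuning = eng.fit(
        X, y, design.output_names_,
        seed=child_seed(seed, "baseline", phenotype),
        cv_folds=cv_folds, n_trials=n_trials,
    )
    return BaselineModel(engine, phenotype, list(covariates), design, eng, tuning)


def compute_residuals(model: BaselineModel, cohort: pd.DataFrame) -> np.ndarray:
    """r_b = y - yhat_b (NaN where the phenotype is masked)."""
    y = cohort[model.phenotype].to_numpy(dtype=float)
    return y - model.predict(cohort)


def fit_genetic(
    train: pd.DataFrame,
    residuals: np.ndarray,
    features: FeatureTable,
    engine: str = "gbt",
    cv_folds: int = 5,
    seed: int = 0,
    covariates=GENETIC_COVARIATES,
    n_trials: int = DEFAULT_N_TRIALS,
) -> GeneticModel:
    """Fit M_g predicting baseline residuals from (x_g, g)."""
    if "study" in covariates:
        raise ValueError("the dataset-specific 'study' covariate is excluded from x_g")
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(train):
        raise ValueError("residuals are misaligned with the cohort table")
    if features is not None and len(features.scores) != len(train):
        raise ValueError("feature table is misaligned with the cohort table")
    ok = ~np.isnan(residuals)
    train_ok = train[ok].reset_index(drop=True)
    feats_ok = (
        FeatureTable(features.scores.iloc[np.flatnonzero(ok)], features.meta)
        if features is not None else None
    )
    design = Design(list(covariates)).fit(train_ok)
    X = design.transform(train_ok)
    F = (
        feats_ok.scores.to_numpy(dtype=float)
        if feats_ok is not None else np.empty((len(train_ok), 0))
    )
    names = design.output_names_ + (feats_ok.columns if feats_ok is not None else [])
    eng = _ENGINES[engine]()
    tuning = eng.fit(
        np.column_stack([X, F]) if (X.size or F.size) else X,
        residuals[ok], names,
        seed=child_seed(seed, "genetic"), cv_folds=cv_folds, n_trials=n_trials,
    )
    meta = features.meta if features is not None else pd.DataFrame(columns=["name"])
    phenotype = ""  # residual-level component; phenotype tracked by the ensemble
    return GeneticModel(engine, phenotype, list(covariates), meta, design, eng, tuning)


def select_local_lasso(
    residuals: np.ndarray,
    local_features: FeatureTable,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[FeatureTable, GeneticModel]:
    """L1 variable selection over local PRS columns.

    Fits LASSO of the baseline residuals on all (standardised) local PRS
    columns, penalty chosen by K-fold CV over a log-spaced grid from the
    analytic lambda_max down by 1e-4.  Returns the columns with nonzero
    coefficients and the fitted sparse model, itself usable as a genetic
    model (the paper-style three-way comparison: LASSO model vs. refit
    linear vs. non-linear model on the selected columns).
    """
    if len(local_features.columns) < 2:
        raise ValueError("need at least two local PRS columns for selection")
    residuals = np.asarray(residuals, dtype=float)
    ok = ~np.isnan(residuals)
    X = local_features.scores.iloc[np.flatnonzero(ok)].to_numpy(dtype=float)
    eng = LassoEngine()
    tuning = eng.fit(
        X, residuals[ok], local_features.columns,
        seed=child_seed(seed, "lasso"), cv_folds=cv_folds,
    )
    selected = [c for c, w in zip(local_features.columns, eng.coef_) if w != 0]
    if not selected:
        warnings.warn("LASSO selected zero local PRS columns")
    model = GeneticModel(
        "lasso", "", [], local_features.meta, Design([]), eng, tuning
    )
    return local_features.select(selected), model


def predict_ensemble(
    model: EnsembleModel, cohort: pd.DataFrame, features: FeatureTable | None
) -> np.ndarray:
    """yhat_ensemble = yhat_b + rhat_b."""
    return model.baseline.predict(cohort) + model.genetic.predict(cohort, features)


def decompose(
    model: EnsembleModel, cohort: pd.DataFrame, features: FeatureTable | None,
) -> pd.DataFrame:
    """Exact decomposition y = yhat_b + rhat_b + r_g on a scored dataset."""
    y = cohort[model.baseline.phenotype].to_numpy(dtype=float)
    y_hat_b = model.baseline.predict(cohort)
    r_hat_b = model.genetic.predict(cohort, features)
    r_g = (y - y_hat_b) - r_hat_b
    return pd.DataFrame({
        "y": y, "y_hat_b": y_hat_b, "r_b": y - y_hat_b,
        "r_hat_b": r_hat_b, "r_g": r_g, "y_hat_ensemble": y_hat_b + r_hat_b,
    })


def calibrate_to_dataset(
    new_cohort: pd.DataFrame,
    genetic: GeneticModel,
    engine: str = "gbt",
    cv_folds: int = 5,
    seed: int = 0,
    phenotype: str = "sbp",
    covariates=BASELINE_COVARIATES,
    n_trials: int = DEFAULT_N_TRIALS,
) -> EnsembleModel:
    """Refit the baseline on a new cohort; reuse the genetic model unchanged.

    The new baseline is fit on the full new cohort without a train/test
    split; the genetic component (trained elsewhere) is attached as-is.
    """
    covariates = [c for c in covariates if c in new_cohort.columns]
    baseline = fit_baseline(
        new_cohort, phenotype, engine=engine, cv_folds=cv_folds,
        seed=seed, covariates=covariates, n_trials=n_trials,
    )
    return EnsembleModel(
        baseline, genetic,
        provenance={"calibrated": True, "seed": seed, "engine": engine},
    )


# -------------------------------------------------------------- persistence

def save_bundle(model: EnsembleModel, path) -> None:
    """JSON envelope: engine payloads + feature/covariate specs + provenance."""

    def _component(m):
        return {
            "engine": m.engine_name,
            "phenotype": m.phenotype,
            "covariates": m.covariates,
            "design": {"columns": m.design.columns, "levels": m.design.levels_,
                       "output_names": m.design.output_names_},
            "payload": m.engine.payload(),
            "tuning": _jsonable(m.tuning),
        }

    bundle = {
        "format": "multiprs-ensemble-v1",
        "baseline": _component(model.baseline),
        "genetic": {
            **_component(model.genetic),
            "feature_meta": model.genetic.feature_meta.to_dict(orient="records"),
        },
        "provenance": _jsonable(model.provenance),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_bundle(path) -> EnsembleModel:
    with open(path) as fh:
        bundle = json.load(fh)

    def _design(d):
        dz = Design(d["columns"])
        dz.levels_ = d["levels"]
        dz.output_names_ = d["output_names"]
        return dz

    def _engine(comp):
        return _ENGINES[comp["engine"]].from_payload(comp["payload"])

    b = bundle["baseline"]
    baseline = BaselineModel(
        b["engine"], b["phenotype"], b["covariates"], _design(b["design"]),
        _engine(b), b.get("tuning", {}),
    )
    g = bundle["genetic"]
    genetic = GeneticModel(
        g["engine"], g["phenotype"], g["covariates"],
        pd.DataFrame(g["feature_meta"]), _design(g["design"]),
        _engine(g), g.get("tuning", {}),
    )
    return EnsembleModel(baseline, genetic, bundle.get("provenance", {}))


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: str(o)))
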