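"""The four presence-background model families, as sklearn-style estimators.

The ensemble combines four complementary binary classifiers of presence (1)
versus background (0):

``linear_logistic``
    unpenalised maximum-likelihood logistic regression with linear terms
    (falls back to a weakly ridge-penalised fit under perfect separation);
``smooth_additive_logistic``
    a binomial additive model with penalised cubic B-splines (~10 basis
    functions per predictor), the common smoothing parameter chosen on a
    grid by generalized cross-validation, GCV = n·deviance/(n − edf)²;
``elastic_net_logistic``
    logistic regression with elastic-net penalty (mixing 0.5), the penalty
    strength chosen by internal 5-fold cross-validation on standardised
    features;
``randomized_tree_ensemble``
    a random forest of 500 trees, floor(sqrt(p)) candidate predictors per
    split, unlimited depth.

No class weighting is applied: the presence:background imbalance of the
sampling design is part of the model contract. All estimators share the
sklearn fit/predict_proba API, accept a DataFrame or array, and are
deterministic given ``random_state``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .grids import EnvironmentalStack, SuitabilityMap
from .predictors import FeatureTable

__all__ = [
    "PresenceBackgroundTable",
    "BaseSDM",
    "LinearLogisticSDM",
    "SmoothAdditiveLogisticSDM",
    "ElasticNetLogisticSDM",
    "RandomForestSDM",
    "FAMILIES",
    "FAMILY_ALIASES",
    "make_sdm",
    "fit",
    "predict_prob",
    "save_model",
    "load_model",
]

SERIALIZATION_VERSION = 1


@dataclass
class PresenceBackgroundTable:
    """Features + binary labels + coordinates for one modelling dataset."""

    features: pd.DataFrame
    labels: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    set_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.features)
        if not (self.labels.size == self.lon.size == self.lat.size == n):
            raise ValueError("features, labels and coordinates disagree in length")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_presence(self) -> int:
        return int(self.labels.sum())

    @property
    def n_background(self) -> int:
        return int((self.labels == 0).sum())

    @classmethod
    def from_parts(
        cls,
        presence: FeatureTable,
        background: FeatureTable,
        set_id: int | None = None,
    ) -> "PresenceBackgroundTable":
        features = pd.concat(
            [presence.features, background.features], ignore_index=True
        )
        labels = np.r_[np.ones(len(presence), int), np.zeros(len(background), int)]
        return cls(
            features=features,
            labels=labels,
            lon=np.r_[presence.lon, background.lon],
            lat=np.r_[presence.lat, background.lat],
            set_id=set_id,
        )

    def subset(self, idx) -> "PresenceBackgroundTable":
        idx = np.asarray(idx)
        return PresenceBackgroundTable(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            lon=self.lon[idx],
            lat=self.lat[idx],
            set_id=self.set_id,
            meta=dict(self.meta),
        )


def _check_fit_inputs(X: pd.DataFrame, y: np.ndarray) -> None:
    if np.isnan(X.to_numpy(float)).any():
        rows = sorted(np.flatnonzero(X.isna().any(axis=1)).tolist())
        raise ValueError(f"missing feature values in rows {rows}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"both classes must be present for fitting; got only {classes.tolist()}"
        )


class BaseSDM(ClassifierMixin, BaseEstimator):
    """Shared fit/predict contract for the four model families."""

    family: str = ""

    def _coerce_X(self, X, reorder: bool = False) -> pd.DataFrame:
        if isinstance(X, FeatureTable):
            X = X.features
        X = pd.DataFrame(X)
        if reorder and hasattr(self, "feature_names_in_"):
            want = list(self.feature_names_in_)
            missing = [c for c in want if c not in X.columns]
            if missing:
                raise ValueError(f"input lacks predictor(s) {missing}")
            X = X[want]
        return X

    def fit(self, X, y):
        X = self._coerce_X(X)
        y = np.asarray(y, dtype=int)
        _check_fit_inputs(X, y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self._fit(X.to_numpy(float), y)
        return self

    def _fit(self, X: np.ndarray, y: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def _predict_p1(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = self._coerce_X(X, reorder=True)
        p1 = np.clip(self._predict_p1(X.to_numpy(float)), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class LinearLogisticSDM(BaseSDM):
    """Unpenalised logistic regression with linear terms only."""

    family = "linear_logistic"

    def __init__(self, max_iter: int = 2000, random_state: int | None = None):
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit(self, X, y):
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=self.max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(X, y)
        p = est.predict_proba(X)[:, 1]
        saturated_separation = (
            p[y == 1].min() > p[y == 0].max()
            and p[y == 1].min() > 1 - 1e-3
            and p[y == 0].max() < 1e-3
        )
        if saturated_separation or any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        ):
            # perfect separation: the unpenalised MLE does not exist, so
            # fall back to a weak ridge penalty
            warnings.warn(
                "linear_logistic hit (near-)perfect separation; "
                "refitting with a weak L2 penalty",
                stacklevel=2,
            )
            est = LogisticRegression(C=100.0, solver="lbfgs", max_iter=self.max_iter)
            est.fit(X, y)
        self.estimator_ = est

    def _predict_p1(self, X):
        return self.estimator_.predict_proba(X)[:, 1]


class SmoothAdditiveLogisticSDM(BaseSDM):
    """Penalised cubic-spline additive logistic model (binomial GAM)."""

    family = "smooth_additive_logistic"

    def __init__(
        self,
        df: int = 10,
        degree: int = 3,
        alphas: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0),
        random_state: int | None = None,
    ):
        self.df = df
        self.degree = degree
        self.alphas = alphas
        self.random_state = random_state

    def _fit(self, X, y):
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        from scipy.linalg import block_diag

        n, p = X.shape
        self._xmin = X.min(axis=0)
        self._xmax = X.max(axis=0)
        smoother = BSplines(X, df=[self.df] * p, degree=[self.degree] * p)
        intercept = np.ones((n, 1))
        design = np.column_stack([intercept, smoother.basis])
        best = None
        for alpha in self.alphas:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = GLMGam(
                        y,
                        exog=intercept,
                        smoother=smoother,
                        alpha=[alpha] * p,
                        family=sm.families.Binomial(),
                    ).fit()
                # effective dof as the penalised hat-matrix trace, computed
                # with a pseudo-inverse (stable under collinear predictors)
                mu = np.asarray(res.fittedvalues)
                w = np.clip(mu * (1.0 - mu), 1e-10, None)
                A = design.T @ (design * w[:, None])
                S = block_diag(
                    np.zeros((1, 1)), *[alpha * m for m in smoother.penalty_matrices]
                )
                edf = float(np.trace(np.linalg.pinv(A + S) @ A))
                if not np.isfinite(edf) or edf >= n:
                    continue
                gcv = n * float(res.deviance) / (n - edf) ** 2
            except Exception:
                continue
            if best is None or gcv < best[0]:
                best = (gcv, alpha, res)
        if best is None:
            raise RuntimeError("smooth_additive_logistic failed for every alpha")
        self.gcv_, self.alpha_, self.result_ = best

    def _predict_p1(self, X):
        # the B-spline basis vanishes outside the training knots; clip there
        Xc = np.clip(X, self._xmin, self._xmax)
        with np.errstate(over="ignore"):
            return np.asarray(
                self.result_.predict(exog=np.ones((X.shape[0], 1)), exog_smooth=Xc)
            )


class ElasticNetLogisticSDM(BaseSDM):
    """Elastic-net logistic regression, penalty tuned by internal 5-fold CV."""

    family = "elastic_net_logistic"

    def __init__(
        self,
        l1_ratio: float = 0.5,
        Cs: int = 10,
        cv: int = 5,
        max_iter: int = 5000,
        random_state: int | None = None,
    ):
        self.l1_ratio = l1_ratio
        self.Cs = Cs
        self.cv = cv
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit(self, X, y):
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegressionCV(
                        solver="saga",
                        l1_ratios=[self.l1_ratio],  # fixed mixing: elastic net
                        Cs=self.Cs,
                        cv=self.cv,
                        scoring="neg_log_loss",
                        max_iter=self.max_iter,
                        tol=1e-3,
                        random_state=self.random_state,
                        use_legacy_attributes=False,
                    ),
                ),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        self.estimator_ = est

    def _predict_p1(self, X):
        return self.estimator_.predict_proba(X)[:, 1]


class RandomForestSDM(BaseSDM):
    """Random forest: 500 trees, sqrt(p) split candidates, unlimited depth."""

    family = "randomized_tree_ensemble"

    def __init__(self, n_estimators: int = 500, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _fit(self, X, y):
        est = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            random_state=self.random_state,
        )
        est.fit(X, y)
        self.estimator_ = est

    def _predict_p1(self, X):
        return self.estimator_.predict_proba(X)[:, 1]


FAMILIES: dict[str, type[BaseSDM]] = {
    "linear_logistic": LinearLogisticSDM,
    "smooth_additive_logistic": SmoothAdditiveLogisticSDM,
    "elastic_net_logistic": ElasticNetLogisticSDM,
    "randomized_tree_ensemble": RandomForestSDM,
}

FAMILY_ALIASES = {
    "glm": "linear_logistic",
    "gam": "smooth_additive_logistic",
    "glmnet": "elastic_net_logistic",
    "rf": "randomized_tree_ensemble",
}


def canonical_family(family: str) -> str:
    family = FAMILY_ALIASES.get(family.lower(), family)
    if family not in FAMILIES:
        raise ValueError(
            f"unknown model family {family!r}; choose from {sorted(FAMILIES)} "
            f"or aliases {sorted(FAMILY_ALIASES)}"
        )
    return family


def make_sdm(family: str, random_state: int | None = None, **params) -> BaseSDM:
    """Instantiate one model family by (canonical or alias) name."""
    cls = FAMILIES[canonical_family(family)]
    return cls(random_state=random_state, **params)


def fit(family: str, table: PresenceBackgroundTable, seed: int | None = None, **params) -> BaseSDM:
    """Fit one family on a presence-background table (thin wrapper)."""
    model = make_sdm(family, random_state=seed, **params)
    model.fit(table.features, table.labels)
    model.meta_ = {
        "family": model.family,
        "predictors": list(model.feature_names_in_),
        "n_presence": table.n_presence,
        "n_background": table.n_background,
        "seed": seed,
    }
    return model


def predict_prob(model: BaseSDM, features) -> np.ndarray | SuitabilityMap:
    """Per-row probabilities for tabular input, a SuitabilityMap for a stack.

    Nodata cells of a stack propagate to nodata in the output map.
    """
    if isinstance(features, EnvironmentalStack):
        missing = [n for n in model.feature_names_in_ if n not in features]
        if missing:
            raise ValueError(f"stack lacks predictor(s) {missing}")
        mask = features.nodata_mask
        rows, cols = np.nonzero(~mask)
        table = pd.DataFrame(
            {n: features[n][rows, cols] for n in model.feature_names_in_}
        )
        out = np.full(features.spec.shape, np.nan)
        out[rows, cols] = model.predict_proba(table)[:, 1]
        return SuitabilityMap(features.spec, out)
    return model.predict_proba(features)[:, 1]


def save_model(model: BaseSDM, path) -> None:
    """Serialize a fitted model with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "serialization_version": SERIALIZATION_VERSION,
        "family": model.family,
        "predictors": list(getattr(model, "feature_names_in_", [])),
        **getattr(model, "meta_", {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path) -> BaseSDM:
    return joblib.load(path)
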