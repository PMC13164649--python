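"""TSS-weighted ensemble of the four model families.

Each family's weight is its mean test TSS (clipped at zero) normalised
across families; the ensemble prediction is the per-cell weighted mean of
the member predictions. Ensemble members are refitted on the full table
before prediction, so the final surface is deterministic given the seed.
Variable importance is permutation-based: the drop in AUC when one
predictor's values are shuffled, computed per family and aggregated with
the ensemble weights. Genus-level composites are cell-wise means across
species maps, displayed via equal-count percentile bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .evaluation import EvaluationRecord, auc, replicate_evaluate
from .grids import EnvironmentalStack, SuitabilityMap
from .models import (
    FAMILIES,
    BaseSDM,
    PresenceBackgroundTable,
    canonical_family,
    fit,
    predict_prob,
)

__all__ = [
    "EnsembleWeights",
    "ImportanceTable",
    "tss_weights",
    "ensemble_predict",
    "EnsembleSDM",
    "fit_ensemble",
    "permutation_importance",
    "composite_mean",
    "percentile_bins",
]


@dataclass
class EnsembleWeights:
    """Per-family convex weights plus the mean test TSS they came from."""

    weights: dict[str, float]
    mean_tss: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("ensemble weights must be >= 0")

    def recompute(self) -> "EnsembleWeights":
        """Round-trip: weights recomputed from the stored provenance."""
        return tss_weights(self.mean_tss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": list(self.weights),
                "mean_tss": [self.mean_tss.get(f, np.nan) for f in self.weights],
                "weight": list(self.weights.values()),
            }
        )


def tss_weights(records) -> EnsembleWeights:
    """Weights proportional to max(mean test TSS, 0) per family.

    ``records`` is either a list of :class:`EvaluationRecord` or a mapping
    family -> mean TSS. All-nonpositive TSS is an error (no family carries
    skill).
    """
    if isinstance(records, dict):
        mean_tss = {canonical_family(f): float(v) for f, v in records.items()}
    else:
        by_family: dict[str, list[float]] = {}
        for rec in records:
            by_family.setdefault(rec.family, []).append(rec.tss)
        if not by_family:
            raise ValueError("no evaluation records supplied")
        mean_tss = {f: float(np.mean(v)) for f, v in by_family.items()}
    clipped = {f: max(v, 0.0) for f, v in mean_tss.items()}
    total = sum(clipped.values())
    if total <= 0:
        raise ValueError("all families have mean TSS <= 0; ensemble is undefined")
    return EnsembleWeights(
        weights={f: v / total for f, v in clipped.items()}, mean_tss=mean_tss
    )


def ensemble_predict(
    maps: dict[str, SuitabilityMap], weights: EnsembleWeights
) -> SuitabilityMap:
    """Per-cell weighted mean of member maps; nodata in any member propagates."""
    missing = [f for f in weights.weights if f not in maps]
    if missing:
        raise ValueError(f"no prediction map for weighted famil(ies) {missing}")
    first = next(iter(maps.values()))
    for m in maps.values():
        if m.spec != first.spec:
            raise ValueError("member maps are not on the same grid")
    out = np.zeros(first.spec.shape)
    for fam, w in weights.weights.items():
        out = out + w * maps[fam].values  # NaN propagates
    return SuitabilityMap(first.spec, out)


class EnsembleSDM(ClassifierMixin, BaseEstimator):
    """TSS-weighted ensemble of the four families, as one sklearn estimator.

    Fitting evaluates each family under the chosen replication scheme to
    obtain its mean test TSS, derives the convex weights, then refits every
    family on the full data. ``predict_proba`` is the weighted mean of the
    member probabilities; :meth:`predict_stack` produces a suitability map
    from an :class:`EnvironmentalStack`.
    """

    def __init__(
        self,
        families: tuple[str, ...] = tuple(FAMILIES),
        weight_scheme: str = "subsample",
        weight_reps: int = 3,
        test_fraction: float = 0.30,
        random_state: int | None = None,
        family_params: dict | None = None,
    ):
        self.families = families
        self.weight_scheme = weight_scheme
        self.weight_reps = weight_reps
        self.test_fraction = test_fraction
        self.random_state = random_state
        self.family_params = family_params

    def _fit_table(self, table: PresenceBackgroundTable) -> "EnsembleSDM":
        rng = np.random.default_rng(self.random_state)
        params = self.family_params or {}
        records: list[EvaluationRecord] = []
        for fam in self.families:
            fam = canonical_family(fam)
            records.extend(
                replicate_evaluate(
                    fam,
                    table,
                    scheme=self.weight_scheme,
                    n_reps=self.weight_reps,
                    test_fraction=self.test_fraction,
                    seed=int(rng.integers(2**31)),
                    **params.get(fam, {}),
                )
            )
        self.records_ = records
        self.weights_ = tss_weights(records)
        self.models_ = {}
        for fam in self.families:
            fam = canonical_family(fam)
            self.models_[fam] = fit(
                fam, table, seed=int(rng.integers(2**31)), **params.get(fam, {})
            )
        first = next(iter(self.models_.values()))
        self.feature_names_in_ = first.feature_names_in_
        self.n_features_in_ = first.n_features_in_
        self.classes_ = np.array([0, 1])
        return self

    def fit(self, X, y, lon=None, lat=None):
        X = pd.DataFrame(X)
        n = len(X)
        table = PresenceBackgroundTable(
            features=X,
            labels=np.asarray(y, dtype=int),
            lon=np.zeros(n) if lon is None else np.asarray(lon, float),
            lat=np.zeros(n) if lat is None else np.asarray(lat, float),
        )
        return self._fit_table(table)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        p1 = np.zeros(len(pd.DataFrame(X)))
        for fam, w in self.weights_.weights.items():
            p1 = p1 + w * self.models_[fam].predict_proba(X)[:, 1]
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_stack(self, stack: EnvironmentalStack) -> SuitabilityMap:
        check_is_fitted(self, "models_")
        maps = {fam: predict_prob(m, stack) for fam, m in self.models_.items()}
        return ensemble_predict(maps, self.weights_)


def fit_ensemble(
    table: PresenceBackgroundTable,
    families: tuple[str, ...] = tuple(FAMILIES),
    weight_scheme: str = "subsample",
    weight_reps: int = 3,
    test_fraction: float = 0.30,
    seed: int | None = None,
    family_params: dict | None = None,
) -> EnsembleSDM:
    """Fit the TSS-weighted ensemble on a presence-background table."""
    ens = EnsembleSDM(
        families=families,
        weight_scheme=weight_scheme,
        weight_reps=weight_reps,
        test_fraction=test_fraction,
        random_state=seed,
        family_params=family_params,
    )
    return ens._fit_table(table)


@dataclass
class ImportanceTable:
    """Permutation importances per family and weight-aggregated."""

    per_family: pd.DataFrame   # index: variable, columns: family, raw values
    aggregated: pd.DataFrame   # columns: importance_raw, importance (floored at 0)

    def ranked(self) -> pd.DataFrame:
        return self.aggregated.sort_values("importance", ascending=False)


def permutation_importance(
    models: dict[str, BaseSDM],
    weights: EnsembleWeights,
    table: PresenceBackgroundTable,
    metric=auc,
    n_perm: int = 10,
    seed: int = 0,
    variables: list[str] | None = None,
) -> ImportanceTable:
    """Mean decrease in the metric when one variable is permuted.

    For each family: metric on the intact table minus the mean metric over
    ``n_perm`` within-column permutations; the aggregate is the
    weight-averaged per-family importance, floored at zero for reporting
    (raw values retained).
    """
    rng = np.random.default_rng(seed)
    X = table.features
    y = table.labels
    if variables is None:
        variables = list(X.columns)
    unknown = [v for v in variables if v not in X.columns]
    if unknown:
        raise ValueError(f"unknown variable(s) {unknown}")
    base = {
        fam: metric(m.predict_proba(X)[:, 1], y) for fam, m in models.items()
    }
    perms = [rng.permutation(len(X)) for _ in range(n_perm)]
    per_family = pd.DataFrame(index=variables, columns=list(models), dtype=float)
    for var in variables:
        for fam, m in models.items():
            drops = []
            for perm in perms:
                Xp = X.copy()
                Xp[var] = X[var].to_numpy()[perm]
                drops.append(base[fam] - metric(m.predict_proba(Xp)[:, 1], y))
            per_family.loc[var, fam] = float(np.mean(drops))
    raw = sum(
        w * per_family[fam] for fam, w in weights.weights.items()
    )
    aggregated = pd.DataFrame(
        {"importance_raw": raw, "importance": raw.clip(lower=0.0)}
    )
    return ImportanceTable(per_family=per_family, aggregated=aggregated)


def composite_mean(maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise mean of several (species) suitability maps."""
    if not maps:
        raise ValueError("composite_mean needs at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.spec != first.spec:
            raise ValueError("maps are not on the same grid")
    values = np.mean([m.values for m in maps], axis=0)
    return SuitabilityMap(first.spec, values)


def percentile_bins(suit: SuitabilityMap, n_bins: int = 6) -> np.ndarray:
    """Classify a map into equal-count percentile bins (1..n_bins, -1 nodata).

    Class c covers the ((c−1)/n, c/n] empirical percentile interval of the
    non-nodata cells; for n = 6 the bin edges sit at the 16.7/33.3/50/66.7/
    83.3 percent points.
    """
    values = suit.values
    finite = values[~np.isnan(values)]
    if np.unique(finite).size < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct values to form {n_bins} percentile bins"
        )
    edges = np.percentile(finite, 100.0 * np.arange(1, n_bins) / n_bins)
    out = np.full(values.shape, -1, dtype=int)
    ok = ~np.isnan(values)
    out[ok] = 1 + np.sum(values[ok][:, None] > edges[None, :], axis=1)
    return out
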