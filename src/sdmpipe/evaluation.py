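"""Model evaluation: discrimination metrics and replication schemes.

Metrics
-------
AUC is the rank-based (Mann-Whitney) probability that a random presence
scores above a random background point, ties counted 1/2. COR is the
point-biserial (Pearson) correlation between scores and the 0/1 labels. TSS
is max over thresholds of sensitivity + specificity − 1 with prediction
rule ``score >= t``, scanning every unique score value (smallest maximiser
returned on ties). Deviance is the mean scaled binomial deviance
−(2/n)·Σ[y·ln p̂ + (1−y)·ln(1−p̂)] with p̂ clipped to [1e−6, 1−1e−6].

Schemes
-------
``subsample`` holds out a stratified 30% test partition per replicate;
``bootstrap`` trains on a with-replacement resample and tests out-of-bag.
Spatial block cross-validation tiles the points with square blocks (default
200 km) in a local azimuthal-equidistant plane and randomly allocates
occupied blocks to k folds, so training and test data are geographically
separated. The null-model test refits the whole pipeline on randomly placed
presences and compares the observed AUC with the 95th percentile of the
null AUC distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import GridSpec, local_xy_km
from .models import PresenceBackgroundTable, fit

__all__ = [
    "EvaluationRecord",
    "FoldAssignment",
    "NullDistribution",
    "auc",
    "point_biserial_cor",
    "tss",
    "binomial_deviance",
    "evaluate_scores",
    "replicate_evaluate",
    "assign_spatial_blocks",
    "spatial_cv",
    "null_model_test",
]


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present")
    return labels, pos


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels, pos = _check_two_class(labels)
    n1 = int(pos.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def point_biserial_cor(scores, labels) -> float:
    """Pearson correlation between scores and the 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels, _ = _check_two_class(labels)
    if np.std(scores) == 0:
        raise ValueError("scores have zero variance")
    return float(np.corrcoef(scores, labels)[0, 1])


def tss(scores, labels) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity − 1.

    Candidate thresholds are the unique score values; the prediction rule is
    ``score >= t``. Returns (tss, threshold), the smallest maximising
    threshold on ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels, pos = _check_two_class(labels)
    thresholds = np.unique(scores)  # ascending
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[~pos])
    n1, n0 = pos_sorted.size, neg_sorted.size
    # count of presences / backgrounds with score >= t
    tp = n1 - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n0 - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n1
    spec = 1.0 - fp / n0
    values = sens + spec - 1.0
    # ties resolve to the smallest threshold; tolerance absorbs float noise
    # (distinct TSS values differ by at least 1/(n1*n0))
    best = int(np.flatnonzero(values >= values.max() - 1e-9)[0])
    return float(values[best]), float(thresholds[best])


def binomial_deviance(scores, labels) -> float:
    """Mean scaled binomial deviance with probability clipping."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    p = np.clip(scores, 1e-6, 1 - 1e-6)
    y = labels
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * ll.mean())


@dataclass
class EvaluationRecord:
    """One replicate's test-set metrics for one model family."""

    family: str
    scheme: str
    replicate: int
    auc: float
    cor: float
    tss: float
    deviance: float
    optimal_threshold: float
    set_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "scheme": self.scheme,
            "replicate": self.replicate,
            "set_id": self.set_id,
            "auc": self.auc,
            "cor": self.cor,
            "tss": self.tss,
            "deviance": self.deviance,
            "optimal_threshold": self.optimal_threshold,
        }


def evaluate_scores(
    scores, labels, family: str, scheme: str, replicate: int, set_id: int | None = None
) -> EvaluationRecord:
    """Bundle all four metrics for one test partition.

    COR is undefined (NaN) when a model scores every row identically.
    """
    t, thr = tss(scores, labels)
    try:
        cor = point_biserial_cor(scores, labels)
    except ValueError:
        cor = float("nan")
    return EvaluationRecord(
        family=family,
        scheme=scheme,
        replicate=replicate,
        set_id=set_id,
        auc=auc(scores, labels),
        cor=cor,
        tss=t,
        deviance=binomial_deviance(scores, labels),
        optimal_threshold=thr,
    )


def _stratified_split(labels: np.ndarray, test_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        n_test = int(round(test_fraction * cls_idx.size))
        test_idx.append(rng.permutation(cls_idx)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


def replicate_evaluate(
    family: str,
    table: PresenceBackgroundTable,
    scheme: str = "subsample",
    n_reps: int = 10,
    test_fraction: float = 0.30,
    seed: int = 0,
    **family_params,
) -> list[EvaluationRecord]:
    """Fit/test replicates under subsampling or bootstrap.

    ``subsample`` draws a stratified ``test_fraction`` test partition per
    replicate; ``bootstrap`` trains on an n-out-of-n resample and tests on
    the out-of-bag rows. Replicates whose partitions end up single-class are
    redrawn (at most 100 attempts each).
    """
    if scheme not in ("subsample", "bootstrap"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(1, n_reps + 1):
        for _attempt in range(100):
            if scheme == "subsample":
                train, test = _stratified_split(table.labels, test_fraction, rng)
            else:
                n = len(table)
                train = rng.integers(0, n, size=n)
                test = np.setdiff1d(np.arange(n), np.unique(train))
            ok = (
                test.size > 0
                and np.unique(table.labels[train]).size == 2
                and np.unique(table.labels[test]).size == 2
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class {scheme} partition in 100 attempts"
            )
        child_seed = int(rng.integers(2**31))
        model = fit(family, table.subset(train), seed=child_seed, **family_params)
        scores = model.predict_proba(table.features.iloc[test])[:, 1]
        records.append(
            evaluate_scores(
                scores, table.labels[test], model.family, scheme, rep, table.set_id
            )
        )
    return records


@dataclass
class FoldAssignment:
    """Per-row fold ids from square spatial blocks; blocks never split."""

    fold: np.ndarray          # per-row fold id in 1..k
    block_id: np.ndarray      # per-row block id
    block_km: float
    k: int
    block_fold: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": np.arange(self.fold.size), "block_id": self.block_id, "fold": self.fold}
        )


def assign_spatial_blocks(
    lon,
    lat,
    labels,
    block_km: float = 200.0,
    k: int = 5,
    seed: int = 0,
    max_attempts: int = 100,
) -> FoldAssignment:
    """Tile points with square blocks and randomly allocate blocks to folds.

    Blocks are laid out in a local azimuthal-equidistant plane about the
    point centroid, so the stated side length is great-circle faithful at
    the few-hundred-km scale. Allocation is redrawn until every fold holds
    at least one presence and one background row.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    labels = np.asarray(labels, dtype=int)
    x, y = local_xy_km(lon, lat)
    bx = np.floor((x - x.min()) / block_km).astype(int)
    by = np.floor((y - y.min()) / block_km).astype(int)
    block_id = bx * (by.max() + 1) + by
    blocks = np.unique(block_id)
    if blocks.size < k:
        raise ValueError(
            f"only {blocks.size} occupied {block_km} km blocks for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        alloc = rng.integers(1, k + 1, size=blocks.size)
        block_fold = dict(zip(blocks.tolist(), alloc.tolist()))
        fold = np.array([block_fold[b] for b in block_id])
        ok = all(
            (labels[fold == f] == 1).any() and (labels[fold == f] == 0).any()
            for f in range(1, k + 1)
        )
        if ok:
            return FoldAssignment(
                fold=fold, block_id=block_id, block_km=block_km, k=k,
                block_fold=block_fold,
            )
    raise RuntimeError(
        f"no valid block-to-fold allocation with presences and background in "
        f"every fold after {max_attempts} attempts"
    )


def spatial_cv(
    family: str,
    table: PresenceBackgroundTable,
    folds: FoldAssignment,
    seed: int = 0,
    **family_params,
) -> tuple[list[tuple[int, float]], float]:
    """Spatially blocked k-fold CV: fit on k−1 folds, AUC on the held-out fold.

    Single-class training or test folds are skipped with a warning; fewer
    than two usable folds is an error. Returns (per-fold AUCs, mean AUC).
    """
    rng = np.random.default_rng(seed)
    per_fold: list[tuple[int, float]] = []
    for f in range(1, folds.k + 1):
        test = np.flatnonzero(folds.fold == f)
        train = np.flatnonzero(folds.fold != f)
        if (
            np.unique(table.labels[train]).size < 2
            or np.unique(table.labels[test]).size < 2
        ):
            warnings.warn(f"fold {f} skipped: single-class partition", stacklevel=2)
            continue
        child_seed = int(rng.integers(2**31))
        model = fit(family, table.subset(train), seed=child_seed, **family_params)
        scores = model.predict_proba(table.features.iloc[test])[:, 1]
        per_fold.append((f, auc(scores, table.labels[test])))
    if len(per_fold) < 2:
        raise RuntimeError("fewer than 2 usable spatial folds")
    mean_auc = float(np.mean([a for _, a in per_fold]))
    return per_fold, mean_auc


@dataclass
class NullDistribution:
    """Null AUCs from randomly placed presences, and the significance call."""

    null_aucs: np.ndarray
    observed_auc: float
    quantile: float = 0.95

    def __post_init__(self) -> None:
        self.null_aucs = np.asarray(self.null_aucs, dtype=float)

    @property
    def critical_value(self) -> float:
        return float(np.percentile(self.null_aucs, 100 * self.quantile))

    @property
    def significant(self) -> bool:
        return bool(self.observed_auc > self.critical_value)


def null_model_test(
    spec: GridSpec,
    n_presences: int,
    pipeline_auc,
    observed_auc: float,
    n_null: int = 99,
    quantile: float = 0.95,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> NullDistribution:
    """Null-model significance test by re-running the pipeline on random points.

    ``pipeline_auc(lon, lat, seed) -> float`` must rerun the full
    fit-and-evaluate pipeline on the supplied presence locations. Presences
    are drawn uniformly without replacement from land (non-nodata) cells.
    Failed null replicates are redrawn, up to 2 × n_null attempts in total.
    """
    if n_null < 19:
        raise ValueError("n_null must be >= 19 for a meaningful 95th percentile")
    ok = np.ones(spec.shape, dtype=bool)
    if nodata_mask is not None:
        ok = ~np.asarray(nodata_mask, dtype=bool)
    rows, cols = np.nonzero(ok)
    if rows.size < n_presences:
        raise ValueError("fewer land cells than requested presences")
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    attempts = 0
    while len(nulls) < n_null:
        if attempts >= 2 * n_null:
            raise RuntimeError(
                f"null pipeline kept failing: {len(nulls)} successes in {attempts} attempts"
            )
        attempts += 1
        idx = rng.choice(rows.size, size=n_presences, replace=False)
        lon, lat = spec.cell_center(rows[idx], cols[idx])
        child_seed = int(rng.integers(2**31))
        try:
            nulls.append(float(pipeline_auc(lon, lat, child_seed)))
        except Exception:
            continue
    return NullDistribution(
        null_aucs=np.asarray(nulls), observed_auc=float(observed_auc), quantile=quantile
    )
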