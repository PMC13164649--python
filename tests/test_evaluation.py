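"""Discrimination metrics against brute-force oracles, replication schemes,
spatial blocking and the null-model test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdmpipe as sp
from sdmpipe.evaluation import (
    NullDistribution,
    assign_spatial_blocks,
    auc,
    binomial_deviance,
    null_model_test,
    point_biserial_cor,
    replicate_evaluate,
    spatial_cv,
    tss,
)
from sdmpipe.grids import GridSpec


# -- independent oracles -----------------------------------------------------

def auc_oracle(scores, labels):
    """Brute-force pair counting over all presence-background pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def tss_oracle(scores, labels):
    """Exhaustive scan over every threshold between consecutive scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    candidates = np.unique(scores)
    best, best_t = -np.inf, None
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        # tolerance: genuinely different TSS values are multiples of
        # 1/(n1*n0); float noise between tied thresholds is ~1e-16
        if sens + spec - 1 > best + 1e-9:
            best, best_t = sens + spec - 1, t
    return best, best_t


class TestAuc:
    def test_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10),
        st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1 = auc(scores, labels)
        a2 = auc(np.exp(5 * scores), labels)  # strictly increasing transform
        assert a1 == pytest.approx(a2)


class TestCor:
    def test_scores_equal_labels(self):
        assert point_biserial_cor([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_scores_equal_inverted_labels(self):
        assert point_biserial_cor([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(-1.0)

    def test_matches_pearson_formula(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        sx = scores - scores.mean()
        sy = labels - labels.mean()
        want = (sx @ sy) / np.sqrt((sx @ sx) * (sy @ sy))
        assert point_biserial_cor(scores, labels) == pytest.approx(want)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            point_biserial_cor([0.5, 0.5], [0, 1])


class TestTss:
    def test_perfect_separation(self):
        value, _ = tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert value == 1.0

    def test_worked_example_value_and_threshold(self):
        value, threshold = tss([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert value == pytest.approx(0.5)
        assert threshold == 0.4  # smallest of the tied maximisers

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        value, _ = tss(scores, labels)
        assert value < 0.08  # permutation oracle: ~0 at large n

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        scores = np.round(rng.random(n), 2)  # induce ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        value, threshold = tss(scores, labels)
        want, want_t = tss_oracle(scores, labels)
        assert value == pytest.approx(want)
        assert threshold == pytest.approx(want_t)


class TestDeviance:
    def test_perfect_fit_near_zero(self):
        assert binomial_deviance([1, 0, 1], [1, 0, 1]) <= 4e-6

    def test_half_probabilities(self):
        assert binomial_deviance([0.5] * 10, [1, 0] * 5) == pytest.approx(2 * np.log(2))

    def test_single_row_closed_form(self):
        assert binomial_deviance([np.exp(-1)], [1]) == pytest.approx(2.0)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            binomial_deviance([1.5], [1])


class TestReplicateEvaluate:
    def test_record_counts_and_partition_size(self, table):
        records = replicate_evaluate(
            "linear_logistic", table, scheme="subsample", n_reps=3, seed=1
        )
        assert len(records) == 3
        assert all(r.scheme == "subsample" for r in records)
        # 30% of each class: 12 presences of 40, 120 background of 400
        # checked indirectly: metrics finite and in range
        for r in records:
            assert 0 <= r.auc <= 1 and -1 <= r.tss <= 1 and r.deviance >= 0

    def test_test_fraction_arithmetic(self):
        from sdmpipe.evaluation import _stratified_split

        labels = np.r_[np.ones(30, int), np.zeros(70, int)]
        rng = np.random.default_rng(0)
        train, test = _stratified_split(labels, 0.30, rng)
        assert test.size == 30  # 9 presences + 21 background
        assert (labels[test] == 1).sum() == 9

    def test_deterministic(self, table):
        a = replicate_evaluate("linear_logistic", table, n_reps=2, seed=7)
        b = replicate_evaluate("linear_logistic", table, n_reps=2, seed=7)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_bootstrap_scheme(self, table):
        records = replicate_evaluate(
            "linear_logistic", table, scheme="bootstrap", n_reps=2, seed=3
        )
        assert len(records) == 2


class TestSpatialBlocks:
    def test_block_grid_geometry(self):
        # points spanning ~600 km x 600 km with 200 km blocks: 9 blocks
        lons = np.array([100.0, 102.7, 105.4])
        lats = np.array([0.0, 2.7, 5.4])  # ~300 km apart at the equator
        lon, lat = np.meshgrid(lons, lats)
        labels = np.tile([0, 1], 5)[:9]
        folds = assign_spatial_blocks(
            lon.ravel(), lat.ravel(), labels, block_km=200.0, k=2, seed=0
        )
        assert np.unique(folds.block_id).size == 9

    def test_nearby_points_share_fold(self):
        lon = np.array([100.0, 100.05, 103.0, 103.05, 100.0, 103.0])
        lat = np.array([5.0, 5.05, 5.0, 5.05, 8.0, 8.0])
        labels = np.array([1, 0, 1, 0, 1, 0])
        folds = assign_spatial_blocks(lon, lat, labels, block_km=200.0, k=2, seed=1)
        assert folds.fold[0] == folds.fold[1]  # ~7 km apart: same block
        assert folds.block_id[0] == folds.block_id[1]

    def test_every_row_assigned_exactly_one_fold(self, table):
        folds = assign_spatial_blocks(
            table.lon, table.lat, table.labels, block_km=30.0, k=3, seed=2
        )
        assert folds.fold.size == len(table)
        assert set(np.unique(folds.fold)) <= set(range(1, 4))

    def test_blocks_never_split_across_folds(self, table):
        folds = assign_spatial_blocks(
            table.lon, table.lat, table.labels, block_km=30.0, k=3, seed=2
        )
        for b in np.unique(folds.block_id):
            assert np.unique(folds.fold[folds.block_id == b]).size == 1

    def test_too_few_blocks_rejected(self):
        lon = np.array([100.0, 100.01, 100.02, 100.03])
        lat = np.array([5.0, 5.01, 5.0, 5.01])
        with pytest.raises(ValueError, match="blocks"):
            assign_spatial_blocks(lon, lat, np.array([1, 0, 1, 0]), 200.0, k=5)


class TestSpatialCV:
    def test_five_folds_give_five_aucs(self, table):
        folds = assign_spatial_blocks(
            table.lon, table.lat, table.labels, block_km=25.0, k=5, seed=3
        )
        per_fold, mean_auc = spatial_cv("linear_logistic", table, folds, seed=0)
        assert len(per_fold) == 5
        assert mean_auc == pytest.approx(np.mean([a for _, a in per_fold]))


class TestNullModel:
    def test_significance_flag_consistent_with_stored_values(self):
        rng = np.random.default_rng(0)
        nulls = rng.uniform(0.4, 0.8, size=99)
        dist = NullDistribution(nulls, observed_auc=1.0)
        assert dist.significant
        assert dist.critical_value == pytest.approx(np.percentile(nulls, 95))
        low = NullDistribution(nulls, observed_auc=float(np.median(nulls)) - 0.01)
        assert not low.significant

    def test_runs_pipeline_closure_and_redraws_failures(self):
        spec = GridSpec(100.0, 10.0, 0.1, 20, 20)
        calls = {"n": 0}

        def closure(lon, lat, seed):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("flaky replicate")
            return float(np.random.default_rng(seed).random())

        dist = null_model_test(
            spec, 10, closure, observed_auc=2.0, n_null=20, seed=1
        )
        assert dist.null_aucs.size == 20
        assert dist.significant

    def test_n_null_floor(self):
        spec = GridSpec(100.0, 10.0, 0.1, 20, 20)
        with pytest.raises(ValueError):
            null_model_test(spec, 5, lambda *a: 0.5, 0.9, n_null=5)
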