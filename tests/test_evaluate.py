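import numpy as np
import pytest
from sklearn.metrics import r2_score

from seqddg.data_io import MutationDataset
from seqddg.evaluate import (
    cross_validate,
    kfold_split,
    label_ascending_split,
    pearson,
    r_squared,
    rank_consistency,
)
from seqddg.network import ModelConfig
from seqddg.train import TrainConfig

from conftest import random_record


class TestPearson:
    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        y = rng.normal(size=6)
        yhat = rng.normal(size=6)
        cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        want = cov / (y.std() * yhat.std())
        assert pearson(y, yhat) == pytest.approx(want, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRSquared:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=8)
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng):
        y = rng.normal(size=8)
        assert r_squared(y, np.full(8, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        y = rng.normal(size=15)
        yhat = y + rng.normal(scale=0.5, size=15)
        assert r_squared(y, yhat) == pytest.approx(r2_score(y, yhat), abs=1e-12)

    def test_squared_pearson_equals_r2_of_fitted_line(self, rng):
        # classical identity: ρ² == R² of the least-squares fit of yhat on y
        y = rng.normal(size=25)
        yhat = 0.6 * y + rng.normal(scale=0.8, size=25)
        slope, intercept = np.polyfit(y, yhat, 1)
        # regress y on yhat and compare fitted values against y
        s2, i2 = np.polyfit(yhat, y, 1)
        fitted = s2 * yhat + i2
        assert pearson(y, yhat) ** 2 == pytest.approx(r_squared(y, fitted), abs=1e-10)
        assert slope != 0  # sanity: the fit is non-degenerate


class TestRankConsistency:
    def test_identical_ordering(self, rng):
        y = rng.normal(size=10)
        assert rank_consistency(y, np.exp(y)) == pytest.approx(1.0)

    def test_reversed_ordering_matches_rank_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        yhat = y[::-1].copy()
        ranks = np.arange(1, 7, dtype=float)
        want = r_squared(ranks, ranks[::-1])
        assert rank_consistency(y, yhat) == pytest.approx(want)

    def test_monotone_transform_invariance(self, rng):
        y = rng.normal(size=12)
        yhat = rng.normal(size=12)
        base = rank_consistency(y, yhat)
        assert rank_consistency(np.tanh(y), yhat) == pytest.approx(base)
        assert rank_consistency(y, 5 * yhat + 2) == pytest.approx(base)

    def test_tied_values_use_average_ranks(self):
        y = np.array([1.0, 1.0, 2.0, 3.0])
        yhat = np.array([1.0, 1.0, 2.0, 3.0])
        assert rank_consistency(y, yhat) == pytest.approx(1.0)


def dataset_of(sizes_and_ddgs):
    """Build a dataset with given {complex_id: [ddg, ...]} labels."""
    records = []
    rng = np.random.default_rng(0)
    for cid, ddgs in sizes_and_ddgs.items():
        for d in ddgs:
            records.append(random_record(rng, complex_id=cid, ddg=float(d)))
    return MutationDataset(records=records, name="fixture")


class TestKFoldSplit:
    def test_fold_sizes_differ_by_at_most_one(self):
        ds = dataset_of({"A": range(10)})
        plan = kfold_split(ds, 5, seed=0)
        sizes = np.bincount(plan.assignments, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_645_records_into_10_folds(self):
        ds = dataset_of({"A": range(645)})
        plan = kfold_split(ds, 10, seed=1)
        sizes = sorted(np.bincount(plan.assignments, minlength=10).tolist())
        assert sizes == [64] * 5 + [65] * 5

    def test_deterministic_and_seed_sensitive(self):
        ds = dataset_of({"A": range(20)})
        a = kfold_split(ds, 4, seed=3).assignments
        b = kfold_split(ds, 4, seed=3).assignments
        c = kfold_split(ds, 4, seed=4).assignments
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert sorted(np.bincount(c, minlength=4).tolist()) == [5, 5, 5, 5]

    def test_folds_partition_dataset(self):
        ds = dataset_of({"A": range(13)})
        plan = kfold_split(ds, 4, seed=0)
        seen = np.concatenate([test for _, test in plan.folds()])
        assert sorted(seen.tolist()) == list(range(13))

    def test_k_out_of_range(self):
        ds = dataset_of({"A": range(5)})
        with pytest.raises(ValueError):
            kfold_split(ds, 1, seed=0)
        with pytest.raises(ValueError):
            kfold_split(ds, 6, seed=0)


class TestLabelAscendingSplit:
    def test_highest_labels_go_to_test(self):
        ds = dataset_of({"A": [-1.0, 0.0, 2.0, 5.0]})
        plan = label_ascending_split(ds, 0.25)
        test_ddgs = [ds.records[i].ddg for i in np.flatnonzero(plan.assignments == 1)]
        assert test_ddgs == [5.0]

    def test_per_complex_ceil_sizes(self):
        ds = dataset_of({"A": range(4), "B": range(6)})
        plan = label_ascending_split(ds, 0.5)
        for cid, want in (("A", 2), ("B", 3)):
            n = sum(
                plan.assignments[i]
                for i, r in enumerate(ds.records)
                if r.complex_id == cid
            )
            assert n == want

    def test_ordering_invariant_within_complex_with_ties(self):
        ds = dataset_of({"A": [1.0, 1.0, 1.0, 2.0, 0.0], "B": [3.0, 3.0, 1.0]})
        plan = label_ascending_split(ds, 0.4)
        for cid in ("A", "B"):
            idx = [i for i, r in enumerate(ds.records) if r.complex_id == cid]
            test = [ds.records[i].ddg for i in idx if plan.assignments[i] == 1]
            train = [ds.records[i].ddg for i in idx if plan.assignments[i] == 0]
            assert min(test) >= max(train)

    def test_singleton_complex_goes_to_train_with_warning(self):
        ds = dataset_of({"A": [1.0], "B": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="single record"):
            plan = label_ascending_split(ds, 0.5)
        only = next(i for i, r in enumerate(ds.records) if r.complex_id == "A")
        assert plan.assignments[only] == 0

    def test_fraction_bounds(self):
        ds = dataset_of({"A": [0.0, 1.0]})
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                label_ascending_split(ds, bad)


@pytest.fixture(scope="module")
def cv_report():
    rng = np.random.default_rng(5)
    records = [random_record(rng, complex_id=f"C{i % 2}", len_ab=9, len_ag=7) for i in range(8)]
    ds = MutationDataset(records=records, name="cv8")
    plan = kfold_split(ds, 2, seed=0)
    mc = ModelConfig(hidden_size=4, n_heads=2, dropout_rate=0.0, fc_sizes=(8, 4, 1), seed=0)
    tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=0)
    return ds, cross_validate(ds, mc, tc, plan)


class TestCrossValidate:

    def test_every_record_predicted_exactly_once(self, cv_report):
        ds, report = cv_report
        assert sorted(report.predictions["index"]) == list(range(8))

    def test_pooled_pcc_is_pearson_over_full_table(self, cv_report):
        _, report = cv_report
        want = pearson(report.predictions["y_true"], report.predictions["y_pred"])
        assert report.pooled_pcc == pytest.approx(want)

    def test_fold_metrics_have_expected_count(self, cv_report):
        _, report = cv_report
        assert len(report.fold_pcc) == 2
        assert len(report.fold_r2) == 2

    def test_plan_must_cover_dataset(self, cv_report):
        ds, _ = cv_report
        short = kfold_split(ds.subset(range(4)), 2, seed=0)
        mc = ModelConfig(hidden_size=4, n_heads=2, fc_sizes=(8, 4, 1))
        with pytest.raises(ValueError, match="cover"):
            cross_validate(ds, mc, TrainConfig(epochs=1), short)
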