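import numpy as np
import pytest

import acpfuse as af
from acpfuse.train_eval import cv_to_dict, make_fold_assignment, write_roc


class TestFoldAssignment:
    def test_stratified_balanced_folds(self):
        labels = [1] * 250 + [0] * 250
        assignment = make_fold_assignment(labels, 10, seed=1)
        y = np.array(labels)
        for fold in range(10):
            mask = assignment == fold
            assert mask.sum() == 50
            assert y[mask].sum() == 25  # 25 positives / 25 negatives per fold

    def test_same_seed_same_assignment(self):
        labels = [1] * 30 + [0] * 30
        a1 = make_fold_assignment(labels, 5, seed=9)
        a2 = make_fold_assignment(labels, 5, seed=9)
        assert np.array_equal(a1, a2)

    def test_stratification_within_one_record(self):
        labels = [1] * 33 + [0] * 67
        assignment = make_fold_assignment(labels, 5, seed=0)
        y = np.array(labels)
        global_frac = y.mean()
        for fold in range(5):
            mask = assignment == fold
            assert abs(y[mask].sum() - global_frac * mask.sum()) <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="class size"):
            make_fold_assignment([1] * 3 + [0] * 50, 5, seed=0)


@pytest.fixture(scope="module")
def small_cv(separable_dataset):
    config = af.ModelConfig(epochs=10, patience=4, seed=5)
    return af.cross_validate(separable_dataset, config, n_folds=5, seed=5), config


class TestCrossValidate:
    def test_folds_partition_dataset(self, small_cv, separable_dataset):
        result, _ = small_cv
        assert result.fold_assignment.shape == (len(separable_dataset),)
        assert len(result.per_fold) == 5
        assert sum(r.counts.total for r in result.per_fold) == len(separable_dataset)

    def test_mean_and_std_over_folds(self, small_cv):
        result, _ = small_cv
        aucs = [r.AUC for r in result.per_fold]
        assert result.mean["AUC"] == pytest.approx(np.mean(aucs))
        assert result.std["AUC"] == pytest.approx(np.std(aucs))

    def test_pooled_report_covers_every_record(self, small_cv, separable_dataset):
        result, _ = small_cv
        assert result.pooled.counts.total == len(separable_dataset)

    def test_machine_readable_summary(self, small_cv):
        result, config = small_cv
        d = cv_to_dict(result)
        assert d["config"] == config.to_dict()
        assert set(d["mean"]) == {"SE", "SP", "ACC", "MCC", "AUC"}
        assert len(d["per_fold"]) == 5


def test_filter_grid_shares_folds(separable_dataset):
    config = af.ModelConfig(epochs=4, seed=3)
    results = af.run_filter_grid(
        separable_dataset, grid=("32", "32-64"), base_config=config, n_folds=3, seed=3
    )
    assert set(results) == {"32", "32-64"}
    a, b = results.values()
    assert np.array_equal(a.fold_assignment, b.fold_assignment)
    assert results["32-64"].config.conv_filters == (32, 64)


def test_empty_grid_rejected(separable_dataset):
    with pytest.raises(ValueError, match="empty"):
        af.run_filter_grid(separable_dataset, grid=())


def test_results_table_layout(separable_dataset):
    config = af.ModelConfig(epochs=4, seed=3)
    results = af.run_filter_grid(
        separable_dataset, grid=("32",), base_config=config, n_folds=3, seed=3
    )
    table = af.results_table(results)
    assert list(table.columns) == ["SE", "SP", "ACC", "MCC", "AUC", "best"]
    assert table.loc["32", "best"]


def test_evaluate_on_test_and_roc_file(tmp_path, separable_dataset, fast_config):
    # positives occupy indices 0..59, negatives 60..119: keep both classes in each split
    train = separable_dataset.subset([*range(0, 50), *range(60, 110)])
    test = separable_dataset.subset([*range(50, 60), *range(110, 120)])
    model = af.train_on_dataset(fast_config, train)
    report = af.evaluate_on_test(model, test)
    assert report.counts.total == 20
    assert 0.0 <= report.ACC <= 1.0
    path = tmp_path / "roc.tsv"
    write_roc(report, path)
    header = path.read_text().splitlines()[0]
    assert header == "FPR\tTPR"
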