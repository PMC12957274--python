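"""Metrics against independent references; fold-generation contracts."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from kansleep.evaluation import (
    ConfusionMatrix,
    cohen_kappa,
    compute_metrics,
    confusion_from_labels,
    make_folds,
    read_confusion_table,
    write_confusion_table,
)


def _expand(cm):
    """Reconstruct (truth, pred) label sequences from a count table."""
    truth, pred = [], []
    for i in range(5):
        for j in range(5):
            truth += [i] * int(cm[i, j])
            pred += [j] * int(cm[i, j])
    return np.array(truth), np.array(pred)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(0, 5, 200)
        cm = confusion_from_labels(truth, truth)
        assert np.trace(cm.counts) == 200
        np.testing.assert_array_equal(np.diag(cm.counts),
                                      np.bincount(truth, minlength=5))

    def test_single_pair(self):
        cm = confusion_from_labels([0], [1])
        assert cm.counts[0, 1] == 1 and cm.total == 1

    def test_matches_brute_force_tally(self, rng):
        truth = rng.integers(0, 5, 1000)
        pred = rng.integers(0, 5, 1000)
        cm = confusion_from_labels(truth, pred)
        brute = np.zeros((5, 5), dtype=int)
        for t, p in zip(truth, pred):
            brute[t, p] += 1
        np.testing.assert_array_equal(cm.counts, brute)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_labels([0, 1], [0])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_labels([0, 5], [0, 0])


class TestMetrics:
    def test_identity_matrix_all_ones(self):
        cm = ConfusionMatrix(np.eye(5, dtype=int) * 10)
        m = compute_metrics(cm)
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0
        np.testing.assert_array_equal(m["f1"], 1.0)
        assert cohen_kappa(cm) == 1.0

    def test_independence_table_zero_kappa(self):
        row = np.array([10, 20, 30, 25, 15])
        col = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        cm = ConfusionMatrix((np.outer(row, col) * 10).astype(int))
        # outer-product tables have p_o == p_e
        assert cohen_kappa(cm) == pytest.approx(0.0, abs=1e-9)

    def test_matches_sklearn_reference(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 50, (5, 5))
            counts[np.arange(5), np.arange(5)] += 1  # every class present
            cm = ConfusionMatrix(counts)
            truth, pred = _expand(counts)
            m = compute_metrics(cm)
            p, r, f, _ = precision_recall_fscore_support(
                truth, pred, labels=range(5), zero_division=np.nan)
            np.testing.assert_allclose(m["precision"], p, atol=1e-9)
            np.testing.assert_allclose(m["recall"], r, atol=1e-9)
            np.testing.assert_allclose(m["f1"][~np.isnan(f)], f[~np.isnan(f)],
                                       atol=1e-9)
            assert cohen_kappa(cm) == pytest.approx(
                cohen_kappa_score(truth, pred, labels=list(range(5))), abs=1e-9)

    def test_absent_class_excluded_from_macro(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10
        counts[1, 1] = 5
        counts[1, 0] = 5
        m = compute_metrics(ConfusionMatrix(counts))
        assert np.isnan(m["f1"][2:]).all()
        f1_w = 2 * (10 / 15) * 1.0 / (10 / 15 + 1.0)
        assert m["macro_f1"] == pytest.approx((f1_w + 2 / 3) / 2, abs=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestTableIO:
    def test_round_trip(self, tmp_path, rng):
        cm = ConfusionMatrix(rng.integers(0, 100, (5, 5)))
        path = tmp_path / "table.txt"
        write_confusion_table(path, cm)
        np.testing.assert_array_equal(read_confusion_table(path).counts, cm.counts)


class TestFolds:
    def test_subject_partition_25_folds(self):
        ids = [f"s{i:02d}" for i in range(50)]
        folds = make_folds(ids, "isruc25", seed=3)
        assert len(folds) == 25
        tested = [s for f in folds for s in f.test_ids]
        assert sorted(tested) == sorted(ids)  # each id tested exactly once
        for f in folds:
            assert len(f.test_ids) == 2 and len(f.val_ids) == 2
            assert not set(f.train_ids) & set(f.test_ids)
            assert not set(f.val_ids) & set(f.test_ids)
            assert set(f.train_ids) | set(f.val_ids) | set(f.test_ids) == set(ids)

    def test_session_folds_sizes(self):
        ids = [f"n{i:03d}" for i in range(153)]
        folds = make_folds(ids, "sleepedf10", seed=1)
        assert len(folds) == 10
        sizes = [len(f.test_ids) for f in folds]
        assert sum(sizes) == 153 and set(sizes) <= {15, 16}
        for f in folds:
            assert len(f.val_ids) == (13 if len(f.test_ids) == 16 else 14)

    def test_wrong_id_count_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a"] * 0 + [f"s{i}" for i in range(49)], "isruc25")
        with pytest.raises(ValueError):
            make_folds([f"n{i}" for i in range(100)], "sleepedf10")

    def test_simple_mode(self):
        ids = [f"r{i}" for i in range(8)]
        folds = make_folds(ids, "simple4", seed=0)
        assert len(folds) == 4
        tested = [s for f in folds for s in f.test_ids]
        assert sorted(tested) == sorted(ids)

    def test_seed_determinism(self):
        ids = [f"s{i:02d}" for i in range(50)]
        a = make_folds(ids, "isruc25", seed=7)
        b = make_folds(ids, "isruc25", seed=7)
        assert [(f.train_ids, f.val_ids, f.test_ids) for f in a] == \
               [(f.train_ids, f.val_ids, f.test_ids) for f in b]
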