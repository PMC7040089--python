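import numpy as np
import pytest

from trbci.decoding import (
    FEATURE_ORDER,
    all_feature_subsets,
    bootstrap_accuracy_se,
    cycles_curve,
    loocv,
    nested_subset_search,
    per_question_accuracy,
    subset_search,
)
from trbci.epochs import FeatureVector, QuestionRecord


def make_records(X, labels, questions=None, participants=None):
    n = len(labels)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    pad = np.zeros((n, 4 - X.shape[1]))
    F = np.hstack([X, pad])
    out = []
    for i in range(n):
        out.append(
            QuestionRecord(
                participant=participants[i] if participants else f"P{i:02d}",
                question_index=questions[i] if questions else (i % 4) + 1,
                features=FeatureVector(*F[i]),
                truth="yes" if labels[i] else "no",
            )
        )
    return out


def separable_records(n_per_class=12, gap=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([
        rng.normal(0.0, 0.2, (n_per_class, 4)),
        rng.normal(gap, 0.2, (n_per_class, 4)),
    ])
    y = [0] * n_per_class + [1] * n_per_class
    return make_records(X, y)


def test_exactly_fifteen_subsets_in_deterministic_order():
    subsets = all_feature_subsets()
    assert len(subsets) == 15
    assert subsets[0] == ("SM",)
    assert subsets[:4] == [("SM",), ("SS",), ("CNR",), ("r",)]
    assert subsets[-1] == ("SM", "SS", "CNR", "r")
    assert len(set(subsets)) == 15


@pytest.mark.parametrize("method", ["LDA", "SVM"])
def test_separable_clouds_classify_perfectly(method):
    """Two point clouds with gap >> spread give 100% LOOCV accuracy."""
    records = separable_records()
    result = loocv(records, FEATURE_ORDER, method)
    assert result.accuracy == 100.0
    assert result.sensitivity == 100.0
    assert result.specificity == 100.0


def test_confusion_matrix_identities(rng):
    X = rng.normal(0.0, 1.0, (30, 4))
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]  # both classes present
    result = loocv(make_records(X, y), FEATURE_ORDER, "SVM")
    (tn, fp), (fn, tp) = result.confusion
    n = tn + fp + fn + tp
    assert n == 30
    assert result.accuracy == pytest.approx(100.0 * (tp + tn) / n)
    assert result.sensitivity == pytest.approx(100.0 * tp / (tp + fn))
    assert result.specificity == pytest.approx(100.0 * tn / (tn + fp))


def test_label_swap_exchanges_sensitivity_and_specificity(rng):
    X = rng.normal(0.0, 1.0, (24, 2))
    X[:12] += 1.0
    y = [1] * 12 + [0] * 12
    a = loocv(make_records(X, y), ("SM", "SS"), "LDA")
    b = loocv(make_records(X, [1 - v for v in y]), ("SM", "SS"), "LDA")
    assert a.accuracy == pytest.approx(b.accuracy)
    assert a.sensitivity == pytest.approx(b.specificity)
    assert a.specificity == pytest.approx(b.sensitivity)


def test_permutation_null_accuracy_is_chance():
    """Uninformative features with permuted labels: mean LOOCV accuracy over
    100 seeds sits within 50% +- 10%."""
    accs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.normal(0.0, 1.0, (24, 2))
        y = rng.permutation([0, 1] * 12)
        res = loocv(make_records(X, y), ("SM", "SS"), "SVM")
        accs.append(res.accuracy)
    assert np.mean(accs) == pytest.approx(50.0, abs=10.0)


def test_manual_fold_walkthrough_matches_nearest_class_mean_lda():
    """Six records, one ambiguous: predictions match an independently coded
    nearest-class-mean rule executed fold by fold (1D LDA, equal priors)."""
    x = np.array([1.0, 1.2, 0.8, -1.0, -0.9, 0.5])
    y = [1, 1, 1, 0, 0, 0]  # 0.5 is an ambiguous 'no'
    records = make_records(x, y)
    result = loocv(records, ("SM",), "LDA")
    expected = []
    for i in range(6):
        keep = [j for j in range(6) if j != i]
        mu1 = np.mean([x[j] for j in keep if y[j] == 1])
        mu0 = np.mean([x[j] for j in keep if y[j] == 0])
        expected.append("yes" if abs(x[i] - mu1) < abs(x[i] - mu0) else "no")
    assert result.per_record_predictions == expected


def test_single_class_dataset_rejected():
    records = make_records(np.arange(4.0), [1, 1, 1, 1])
    with pytest.raises(ValueError):
        loocv(records, ("SM",), "SVM")


def test_subset_search_finds_the_informative_feature(rng):
    """Only r carries signal; the best subset must contain r."""
    n = 24
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0.0, 1.0, (n, 4))
    X[:, 3] = y * 5.0 + rng.normal(0.0, 0.2, n)
    report = subset_search(make_records(X, y), "SVM")
    assert len(report.results) == 15
    assert "r" in report.best_subset
    assert report.best_accuracy == max(r.accuracy for r in report.results)


def test_equal_accuracy_ties_resolve_by_documented_order():
    """A duplicated informative column produces ties; the winner is the
    earliest subset in fewest-first, SM<SS<CNR<r order."""
    rng = np.random.default_rng(3)
    n = 20
    y = np.array([0, 1] * (n // 2))
    signal = y * 8.0 + rng.normal(0.0, 0.1, n)
    X = np.column_stack([signal, signal, rng.normal(0, 1, n), rng.normal(0, 1, n)])
    report = subset_search(make_records(X, y), "LDA")
    assert report.best_subset == ("SM",)  # first of the tied singletons


def test_per_question_accuracy_partitions_overall(rng):
    X = rng.normal(0.0, 1.0, (24, 4))
    X[::2] += 3.0
    y = [1, 0] * 12
    questions = [(i % 4) + 1 for i in range(24)]
    records = make_records(X, y, questions=questions)
    result = loocv(records, FEATURE_ORDER, "SVM")
    per_q = per_question_accuracy(records, result)
    assert set(per_q) == {1, 2, 3, 4}
    assert np.mean(list(per_q.values())) == pytest.approx(result.accuracy)


def test_empty_question_position_is_reported_as_undefined(rng):
    X = rng.normal(0.0, 1.0, (8, 4))
    X[:4] += 3.0
    records = make_records(X, [1, 1, 1, 1, 0, 0, 0, 0], questions=[1, 1, 2, 2, 1, 1, 2, 2])
    result = loocv(records, FEATURE_ORDER, "SVM")
    per_q = per_question_accuracy(records, result)
    assert 3 not in per_q  # no records at position 3: absent, not zero


def test_noise_free_position_dominates(rng):
    """Records at position 1 are noiseless and separable; their accuracy is
    at least that of the noisy positions."""
    n = 32
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0.0, 1.5, (n, 1))
    questions = [(i % 4) + 1 for i in range(n)]
    for i in range(n):
        if questions[i] == 1:
            X[i, 0] = y[i] * 6.0
        else:
            X[i, 0] += y[i] * 1.0
    records = make_records(X, y, questions=questions)
    result = loocv(records, ("SM",), "LDA")
    per_q = per_question_accuracy(records, result)
    assert per_q[1] >= max(per_q[2], per_q[3], per_q[4]) - 1e-9


def test_cycles_curve_consistency_at_full_cycles(rng):
    records = separable_records()
    records_by_k = {k: records for k in range(1, 6)}
    curve = cycles_curve(records_by_k, "SVM")
    report = subset_search(records, "SVM")
    assert curve.fixed_subset == report.best_subset
    assert curve.fixed_subset_accuracy[5] == report.best_accuracy
    assert set(curve.per_subset[1]) == set(
        tuple(s) for s in map(tuple, (r.feature_subset for r in report.results))
    )


def test_loocv_is_deterministic(rng):
    X = rng.normal(0.0, 1.0, (20, 4))
    y = [0, 1] * 10
    records = make_records(X, y)
    a = loocv(records, FEATURE_ORDER, "SVM")
    b = loocv(records, FEATURE_ORDER, "SVM")
    assert a.per_record_predictions == b.per_record_predictions


def test_nested_search_not_above_plain_on_separable_data():
    records = separable_records()
    nested = nested_subset_search(records, "LDA")
    assert nested == 100.0  # fully separable: selection bias is irrelevant


def test_bootstrap_se_is_zero_for_perfect_predictions():
    records = separable_records(6)
    preds = [r.truth for r in records]
    assert bootstrap_accuracy_se(records, preds) == 0.0
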