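"""Yes/no decoding: LDA and linear SVM with leave-one-out cross-validation.

Records are pooled across participants (one record per question run).  For
every left-out record the classifier is trained on the remaining N-1 with
features standardised by the training-fold mean/SD.  The exhaustive subset
search evaluates all 15 non-empty subsets of {SM, SS, CNR, r} and reports
the argmax; selecting by LOOCV accuracy mirrors common practice but is
optimistically biased, so a nested variant is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .epochs import QuestionRecord

FEATURE_ORDER = ("SM", "SS", "CNR", "r")
POSITIVE = "yes"


def all_feature_subsets() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets, ordered fewest-features-first then
    lexicographically in SM < SS < CNR < r (the deterministic tie order)."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(FEATURE_ORDER) + 1):
        out.extend(combinations(FEATURE_ORDER, k))
    return out


@dataclass
class DecodingResult:
    method: str
    feature_subset: tuple[str, ...]
    accuracy: float      # %
    sensitivity: float   # %, yes = positive class
    specificity: float   # %
    per_record_predictions: list[str]
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    majority_folds: int = 0


@dataclass
class SubsetSearchReport:
    results: list[DecodingResult]
    best_subset: tuple[str, ...]
    best_accuracy: float

    def __post_init__(self):
        if len(self.results) != 15:
            raise ValueError("subset search must evaluate exactly 15 subsets")


def _make_classifier(method: str):
    if method == "LDA":
        return LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    if method == "SVM":
        return SVC(kernel="linear", C=1.0, tol=1e-5)
    raise ValueError(f"unknown method {method!r}; use 'LDA' or 'SVM'")


def _feature_matrix(records: list[QuestionRecord], subset: tuple[str, ...]) -> np.ndarray:
    return np.stack([r.features.as_array(subset) for r in records])


def loocv(
    records: list[QuestionRecord],
    subset: tuple[str, ...] = FEATURE_ORDER,
    method: str = "SVM",
) -> DecodingResult:
    """Leave-one-out cross-validation over pooled question records.

    Training folds that collapse to a single class predict the majority
    class of the fold and are counted in ``majority_folds``.
    """
    if len(records) < 2:
        raise ValueError("LOOCV needs at least two records")
    y = np.array([r.truth == POSITIVE for r in records])
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    X = _feature_matrix(records, subset)
    n = len(records)
    pred = np.zeros(n, dtype=bool)
    majority = 0
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        if ytr.all() or not ytr.any():
            pred[i] = ytr.mean() >= 0.5
            majority += 1
            continue
        clf = _make_classifier(method)
        clf.fit((Xtr - mu) / sd, ytr)
        pred[i] = bool(clf.predict(((X[i] - mu) / sd)[None, :])[0])
    tp = int(np.count_nonzero(pred & y))
    tn = int(np.count_nonzero(~pred & ~y))
    fp = int(np.count_nonzero(pred & ~y))
    fn = int(np.count_nonzero(~pred & y))
    result = DecodingResult(
        method=method,
        feature_subset=tuple(subset),
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        per_record_predictions=[POSITIVE if p else "no" for p in pred],
        confusion=np.array([[tn, fp], [fn, tp]]),
        majority_folds=majority,
    )
    return result


def subset_search(records: list[QuestionRecord], method: str = "SVM") -> SubsetSearchReport:
    """Evaluate every non-empty feature subset by LOOCV; report the argmax.

    Accuracy ties are broken by the subset order (fewest features first,
    then lexicographic in SM < SS < CNR < r).
    """
    results = [loocv(records, subset, method) for subset in all_feature_subsets()]
    best = max(results, key=lambda res: res.accuracy)  # max is stable: first argmax
    return SubsetSearchReport(results, best.feature_subset, best.accuracy)


def nested_subset_search(records: list[QuestionRecord], method: str = "SVM") -> float:
    """Unbiased accuracy: the subset is re-selected inside every outer fold."""
    n = len(records)
    correct = 0
    for i in range(n):
        inner = [r for j, r in enumerate(records) if j != i]
        report = subset_search(inner, method)
        res = loocv(records, report.best_subset, method)
        correct += res.per_record_predictions[i] == records[i].truth
    return 100.0 * correct / n


def per_question_accuracy(
    records: list[QuestionRecord], result: DecodingResult
) -> dict[int, float | None]:
    """Descriptive LOOCV accuracy per question-order position (1-based).

    Positions with no records are reported as None, not zero.
    """
    out: dict[int, float | None] = {}
    positions = sorted({r.question_index for r in records})
    for pos in positions:
        idx = [i for i, r in enumerate(records) if r.question_index == pos]
        if not idx:
            out[pos] = None
            continue
        hits = sum(result.per_record_predictions[i] == records[i].truth for i in idx)
        out[pos] = 100.0 * hits / len(idx)
    return out


@dataclass
class CyclesCurve:
    """Accuracy as a function of the number of cycles used for epoching."""

    per_subset: dict[int, dict[tuple[str, ...], float]] = field(default_factory=dict)
    fixed_subset: tuple[str, ...] = FEATURE_ORDER
    fixed_subset_accuracy: dict[int, float] = field(default_factory=dict)

    @property
    def ks(self) -> list[int]:
        return sorted(self.fixed_subset_accuracy)


def cycles_curve(
    records_by_k: dict[int, list[QuestionRecord]], method: str = "SVM"
) -> CyclesCurve:
    """Re-run the subset search for epochs built from the first k cycles only.

    ``records_by_k`` maps k -> the feature records extracted with k cycles;
    the curve also tracks the subset that is optimal at the largest k.
    """
    ks = sorted(records_by_k)
    curve = CyclesCurve()
    reports = {k: subset_search(records_by_k[k], method) for k in ks}
    curve.fixed_subset = reports[ks[-1]].best_subset
    for k in ks:
        curve.per_subset[k] = {
            res.feature_subset: res.accuracy for res in reports[k].results
        }
        curve.fixed_subset_accuracy[k] = curve.per_subset[k][curve.fixed_subset]
    return curve


def bootstrap_accuracy_se(
    records: list[QuestionRecord],
    predictions: list[str],
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a LOOCV accuracy (resampling records)."""
    rng = np.random.default_rng(seed)
    hits = np.array([p == r.truth for p, r in zip(predictions, records)], dtype=float)
    n = hits.size
    samples = rng.integers(0, n, size=(n_boot, n))
    return float((100.0 * hits[samples].mean(axis=1)).std(ddof=1))
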