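"""kNN and dissimilarity-space SVM classification with L1O/L6O crossvalidation.

Classifier quality on this problem is reported as a *loss pattern* — the
identity set of misclassified records under crossvalidation — rather than a
scalar rate: with ~23 records the informative comparison is which records a
method misses.  kNN operates directly on a precomputed protein distance
matrix; the SVM embeds each record as its vector of distances to the
training records (dissimilarity space) under an RBF kernel.  Distances carry
no label information, so precomputed matrices are reused across folds with
held-out records masked from neighbor/reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .ts_distance import DistanceMatrix, DistanceSpec, distance_matrix

__all__ = [
    "LossPattern",
    "CVPlan",
    "make_l1o",
    "make_l6o",
    "knn_classify",
    "crossvalidate",
    "crossvalidate_knn",
    "crossvalidate_svm",
    "rank_distance_functions",
    "rbf_gamma_heuristic",
    "svm_train",
    "reference_point_kernel",
]


@dataclass(frozen=True)
class LossPattern:
    """Set of misclassified record IDs; false positives are the subset whose
    true label is negative."""

    missed: frozenset[str]
    false_positives: frozenset[str]

    def __post_init__(self) -> None:
        if not self.false_positives <= self.missed:
            raise ValueError("false_positives must be a subset of missed")

    @property
    def n_errors(self) -> int:
        return len(self.missed)

    def key(self) -> tuple[str, ...]:
        """Canonical sortable identity of the pattern."""
        return tuple(sorted(self.missed))

    def format(self) -> str:
        """Render as a comma-separated ID list with false positives starred."""
        return ", ".join(
            f"{i}*" if i in self.false_positives else i for i in sorted(self.missed)
        ) or "-"


@dataclass(frozen=True)
class CVPlan:
    """An explicit crossvalidation partition of record IDs."""

    scheme: str
    folds: tuple[tuple[str, ...], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        flat = [i for fold in self.folds for i in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds must partition the IDs (duplicate found)")


def make_l1o(ids: Sequence[str]) -> CVPlan:
    """Leave-one-out plan: one singleton fold per record."""
    return CVPlan(scheme="L1O", folds=tuple((i,) for i in ids))


def make_l6o(ids: Sequence[str], seed: int, fold_size: int = 6) -> CVPlan:
    """Leave-six-out plan: seeded random partition into folds of six
    (the final fold may be smaller)."""
    rng = np.random.default_rng(seed)
    perm = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
    folds = tuple(
        tuple(perm[i : i + fold_size]) for i in range(0, len(perm), fold_size)
    )
    return CVPlan(scheme="L6O", folds=folds, seed=seed)


def knn_classify(
    dist: DistanceMatrix,
    labels: Mapping[str, int],
    query_id: str,
    k: int = 3,
    train_ids: Iterable[str] | None = None,
) -> int:
    """Majority vote among the k nearest training records.

    The query is never its own neighbor; distance ties break to the smallest
    record ID, making the classifier fully deterministic.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    pool = [i for i in (train_ids if train_ids is not None else dist.ids) if i != query_id]
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} available training records")
    qi = dist.ids.index(query_id)
    ranked = sorted(pool, key=lambda i: (dist.values[qi, dist.ids.index(i)], i))
    votes = [labels[i] for i in ranked[:k]]
    return int(sum(votes) * 2 > k)


def crossvalidate(
    predict_fold: Callable[[tuple[str, ...], tuple[str, ...]], Mapping[str, int]],
    labels: Mapping[str, int],
    plan: CVPlan,
) -> LossPattern:
    """Run a crossvalidation plan and collect the loss pattern.

    ``predict_fold(train_ids, test_ids)`` returns predicted labels for the
    test IDs after training only on the train IDs.
    """
    all_ids = {i for fold in plan.folds for i in fold}
    unknown = all_ids - set(labels)
    if unknown:
        raise ValueError(f"plan references unknown IDs: {sorted(unknown)}")
    missed, false_pos = set(), set()
    for fold in plan.folds:
        train = tuple(i for i in sorted(all_ids - set(fold)))
        preds = predict_fold(train, fold)
        for i in fold:
            if preds[i] != labels[i]:
                missed.add(i)
                if labels[i] == 0:
                    false_pos.add(i)
    return LossPattern(missed=frozenset(missed), false_positives=frozenset(false_pos))


def crossvalidate_knn(
    dist: DistanceMatrix, labels: Mapping[str, int], plan: CVPlan, k: int = 3
) -> LossPattern:
    """Crossvalidated kNN on a precomputed distance matrix."""

    def predict_fold(train, fold):
        return {i: knn_classify(dist, labels, i, k=k, train_ids=train) for i in fold}

    return crossvalidate(predict_fold, labels, plan)


def rbf_gamma_heuristic(features: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise feature distance:
    gamma = 1 / (2 * median^2)."""
    from scipy.spatial.distance import pdist

    d = pdist(features)
    d = d[d > 0]
    med = float(np.median(d)) if d.size else 1.0
    return 1.0 / (2.0 * med * med) if med > 0 else 1.0


def svm_train(features: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | None = None) -> SVC:
    """Soft-margin RBF SVM on reference-distance feature vectors."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if gamma is None:
        gamma = rbf_gamma_heuristic(np.asarray(features, dtype=float))
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(features, y)
    return clf


def crossvalidate_svm(
    dist: DistanceMatrix, labels: Mapping[str, int], plan: CVPlan, C: float = 1.0
) -> LossPattern:
    """Crossvalidated dissimilarity-space SVM.

    Per fold, the reference panel is exactly the training set: a record's
    feature vector lists its distances to each training record, so held-out
    records never appear as reference points.
    """
    idx = {i: n for n, i in enumerate(dist.ids)}

    def predict_fold(train, fold):
        cols = [idx[t] for t in train]
        x_train = dist.values[np.ix_([idx[t] for t in train], cols)]
        y_train = np.array([labels[t] for t in train])
        clf = svm_train(x_train, y_train)
        x_test = dist.values[np.ix_([idx[q] for q in fold], cols)]
        preds = clf.predict(x_test)
        return dict(zip(fold, (int(p) for p in preds)))

    return crossvalidate(predict_fold, labels, plan)


def rank_distance_functions(
    series_sets,
    labels: Mapping[str, int],
    metrics: Sequence[str] = ("dtw", "lcss", "mvm"),
    ks: Sequence[int] = (1, 3, 5),
    plans: Sequence[CVPlan] | None = None,
    epsilons: dict[int, float] | None = None,
    n_indices: int = 7,
) -> pd.DataFrame:
    """Exhaustively rank elastic distance functions by kNN crossvalidation error.

    Uses the full distance sum over every loop and index; returns one row per
    (metric, k, scheme) cell sorted by errors ascending with metric name as
    the tie-break.
    """
    if plans is None:
        plans = [make_l1o([s.record_id for s in series_sets])]
    rows = []
    for metric in metrics:
        spec = DistanceSpec(metric=metric, indices=tuple(range(1, n_indices + 1)))
        dmat = distance_matrix(series_sets, spec, epsilons)
        for k in ks:
            for plan in plans:
                loss = crossvalidate_knn(dmat, labels, plan, k=k)
                rows.append(
                    {
                        "metric": metric,
                        "k": k,
                        "scheme": plan.scheme,
                        "n_errors": loss.n_errors,
                        "missed": loss.format(),
                    }
                )
    out = pd.DataFrame(rows).sort_values(
        ["n_errors", "metric", "k", "scheme"], kind="stable"
    )
    return out.reset_index(drop=True)


def reference_point_kernel(dist: DistanceMatrix, origin_id: str, tol: float = 1e-8):
    """Documented utility: the reference-point kernel
    k_O(x, y) = (1/2)(-d^2(x,y) + d^2(x,x_O) + d^2(y,x_O)).

    Returns the Gram matrix over all records and whether it is positive
    semidefinite within tolerance.  With a non-metric distance such as DTW the
    matrix may fail PSD, which is why the dissimilarity-space feature-vector
    route is the default classifier instead.
    """
    o = dist.ids.index(origin_id)
    d2 = dist.values**2
    gram = 0.5 * (-d2 + d2[:, [o]] + d2[[o], :])
    eig = np.linalg.eigvalsh((gram + gram.T) / 2)
    return gram, bool(eig.min() >= -tol * max(1.0, abs(eig.max())))
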