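"""Evaluation protocol: grouped k-fold CV, undersampling, accuracy, AUROC.

The cross-validation is group-respecting — all samples sharing a group id
(e.g. one patient) land in a single fold — and random undersampling of the
majority class is applied inside each training split only, never to the test
split, so no information leaks across the fold boundary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import model as model_mod

__all__ = [
    "grouped_kfold",
    "undersample",
    "auroc",
    "cross_validate",
    "KnnBaseline",
    "grid_search",
]

logger = logging.getLogger(__name__)


def grouped_kfold(groups: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Assign each sample to one of ``k`` folds without splitting any group.

    Groups are shuffled (per seed), then greedily dealt — largest first — to
    the currently smallest fold by sample count, which keeps fold sizes as
    balanced as the group sizes allow.  Returns a fold id per sample.
    """
    groups = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    if uniq.shape[0] < k:
        raise ValueError(f"need at least {k} distinct groups, got {uniq.shape[0]}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.shape[0])
    # stable sort by size (descending) keeps the shuffled order among ties
    order = order[np.argsort(-counts[order], kind="stable")]
    fold_of_group = np.empty(uniq.shape[0], dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for g in order:
        f = int(np.argmin(fold_sizes))
        fold_of_group[g] = f
        fold_sizes[f] += counts[g]
    return fold_of_group[inv]


def undersample(
    labels: np.ndarray,
    groups: np.ndarray | None,
    min_ratio: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Randomly drop majority samples until minority/majority >= ``min_ratio``.

    Binary labels only.  If the ratio already satisfies the bound the input
    indices are returned unchanged.  Majority samples are removed uniformly
    at random down to the largest count ``c`` with ``minority / c >=
    min_ratio``; minority samples are never removed.  Returns the sorted
    kept-sample index array.
    """
    labels = np.asarray(labels)
    if not 0 < min_ratio <= 1:
        raise ValueError("min_ratio must be in (0, 1]")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.shape[0] != 2:
        raise ValueError(f"undersample requires binary labels, got {classes.shape[0]} class(es)")
    minority_cls = classes[np.argmin(counts)]
    majority_cls = classes[np.argmax(counts)]
    n_min, n_maj = int(counts.min()), int(counts.max())
    if n_min / n_maj >= min_ratio:
        return np.arange(labels.shape[0])
    target = int(np.floor(n_min / min_ratio + 1e-12))
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(labels == majority_cls)
    keep_maj = rng.choice(maj_idx, size=target, replace=False)
    kept = np.sort(np.concatenate([np.flatnonzero(labels == minority_cls), keep_maj]))
    logger.info(
        "undersampled class %r from %d to %d samples (seed=%d)",
        majority_cls, n_maj, target, seed,
    )
    return kept


def auroc(true_labels: np.ndarray, scores: np.ndarray, positive_class=None) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals ``P(score+ > score-) + 0.5 * P(tie)``.  ``positive_class``
    defaults to the larger of the two label values.
    """
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(true_labels)
    if classes.shape[0] != 2:
        raise ValueError("AUROC needs exactly 2 classes present")
    if positive_class is None:
        positive_class = classes[-1]
    pos = true_labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


class KnnBaseline:
    """Plain Euclidean k-nearest-neighbors comparator (majority vote).

    Deliberately simple and self-contained; used only as the reference point
    for the heavy-tail robustness comparisons.
    """

    def __init__(self, k: int = 7):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnBaseline":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        self._classes = np.unique(self._y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        k = min(self.k, self._X.shape[0])
        nn = np.argpartition(d2, k - 1, axis=1)[:, :k]
        votes = self._y[nn]
        probs = np.stack(
            [(votes == c).mean(axis=1) for c in self._classes], axis=1
        )
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._classes[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class EvaluationReport:
    """Per-fold and aggregate CV metrics plus the configuration that made them."""

    fold_accuracy: list[float]  # percent
    fold_auroc: list[float | None]
    mean_accuracy: float
    mean_auroc: float | None
    class_counts_before: dict
    class_counts_after: list[dict]
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": self.fold_accuracy,
            "fold_auroc": self.fold_auroc,
            "mean_accuracy": self.mean_accuracy,
            "mean_auroc": self.mean_auroc,
            "class_counts_before": self.class_counts_before,
            "class_counts_after": self.class_counts_after,
            "config": self.config,
            "seed": self.seed,
        }


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    capital_lambda: float = 1.0,
    capital_theta: float = 1.0,
    reweight: bool = False,
    min_ratio: float | None = 0.3,
    std_ddof: int = 0,
) -> EvaluationReport:
    """Group-respecting k-fold cross-validation of the kernel classifier.

    Undersampling (binary labels, when ``min_ratio`` is given) is applied to
    each training split only.  Binary AUROC uses the positive-class
    probability, where "positive" is the larger label value; a test fold
    with a single class gets a missing AUROC and a log warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if groups is None:
        groups = np.arange(X.shape[0])  # each sample its own group
    folds = grouped_kfold(groups, k, seed=seed)
    classes = np.unique(labels)
    binary = classes.shape[0] == 2

    accs: list[float] = []
    aurocs: list[float | None] = []
    counts_after: list[dict] = []
    for f in range(k):
        test = folds == f
        train = ~test
        train_idx = np.flatnonzero(train)
        if binary and min_ratio is not None:
            kept = undersample(labels[train_idx], groups[train_idx], min_ratio, seed=seed + f)
            train_idx = train_idx[kept]
        cls, cnt = np.unique(labels[train_idx], return_counts=True)
        counts_after.append({str(c): int(v) for c, v in zip(cls, cnt)})

        mdl = model_mod.fit(
            X[train_idx],
            labels[train_idx],
            capital_lambda=capital_lambda,
            capital_theta=capital_theta,
            reweight=reweight,
            std_ddof=std_ddof,
        )
        probs = mdl.predict_proba(X[test])
        preds = mdl.classes[np.argmax(probs, axis=1)]
        accs.append(100.0 * float(np.mean(preds == labels[test])))
        if binary:
            if np.unique(labels[test]).shape[0] < 2:
                logger.warning("fold %d has a single class in the test split; AUROC skipped", f)
                aurocs.append(None)
            else:
                pos = classes[-1]
                pos_col = int(np.flatnonzero(mdl.classes == pos)[0])
                aurocs.append(auroc(labels[test], probs[:, pos_col], positive_class=pos))
        else:
            aurocs.append(None)

    valid_aurocs = [a for a in aurocs if a is not None]
    cls_b, cnt_b = np.unique(labels, return_counts=True)
    return EvaluationReport(
        fold_accuracy=accs,
        fold_auroc=aurocs,
        mean_accuracy=float(np.mean(accs)),
        mean_auroc=float(np.mean(valid_aurocs)) if valid_aurocs else None,
        class_counts_before={str(c): int(v) for c, v in zip(cls_b, cnt_b)},
        class_counts_after=counts_after,
        config={
            "k": k,
            "capital_lambda": capital_lambda,
            "capital_theta": capital_theta,
            "reweight": reweight,
            "min_ratio": min_ratio,
            "std_ddof": std_ddof,
        },
        seed=seed,
    )


def grid_search(
    X: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray | None = None,
    lambdas: tuple[float, ...] = (0.1, 1.0, 10.0),
    thetas: tuple[float, ...] = (0.5, 1.0, 2.0),
    k: int = 5,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, float, EvaluationReport]:
    """Pick (capital_lambda, capital_theta) by cross-validated accuracy.

    Returns the best pair and its report.  Meant to be nested inside an
    outer CV when used for model selection.
    """
    best = None
    for lam in lambdas:
        for th in thetas:
            rep = cross_validate(
                X, labels, groups, k=k, seed=seed,
                capital_lambda=lam, capital_theta=th, **cv_kwargs,
            )
            key = rep.mean_accuracy
            if best is None or key > best[0]:
                best = (key, lam, th, rep)
    assert best is not None
    return best[1], best[2], best[3]


def fit_timing(
    m_values: tuple[int, ...],
    n_features: int = 4,
    seed: int = 0,
    repeats: int = 5,
) -> dict[int, float]:
    """Best-of-``repeats`` wall-clock fit times over training sizes.

    Used for empirical complexity checks; the minimum over repeats damps
    scheduler noise.
    """
    from .synthetic import SimulationConfig, generate

    times: dict[int, float] = {}
    for m in m_values:
        cfg = SimulationConfig(
            n_features=n_features, n_informative=n_features,
            class_counts=(m // 2, m - m // 2), seed=seed,
        )
        X, y, _ = generate(cfg)
        model_mod.fit(X, y)  # warm-up
        best = np.inf
        for _ in range(repeats):
            t0 = time.perf_counter()
            model_mod.fit(X, y)
            best = min(best, time.perf_counter() - t0)
        times[m] = best
    return times
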