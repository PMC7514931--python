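"""Fitting and prediction for the concave/convex-kernel classifier.

Training consists of three closed-form estimation steps on the stored
training matrix:

1. per-feature length scales ``lam_i = capital_lambda / s_i**2`` from the
   feature standard deviations;
2. per-feature relevance scores ``alpha_i``: the total leave-one-out gap
   between average within-class and average overall single-feature
   similarity, floored at zero;
3. per-feature exponents ``theta_i`` proportional to ``alpha_i`` and summing
   to ``n * capital_theta`` over the non-constant features.

The model is instance-based: prediction sums kernel similarities between the
query and every stored training row, class by class, and picks the class
with the largest (optionally reweighted) sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernel import KernelParams, log_similarity_matrix

__all__ = [
    "LucckModel",
    "estimate_lambdas",
    "estimate_alphas",
    "estimate_thetas",
    "fit",
]

_FORMAT_VERSION = "lucck-model-1"


def estimate_lambdas(
    X: np.ndarray,
    capital_lambda: float = 1.0,
    ddof: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature length scales from column standard deviations.

    Parameters
    ----------
    X : ndarray of shape (m, n)
        Training matrix, ``m >= 2``.
    capital_lambda : float
        Global scale; ``lam_i = capital_lambda / s_i**2``.
    ddof : int
        Delta degrees of freedom for the standard deviation (0 = population
        convention, the package default; 1 = sample convention).

    Returns
    -------
    lambdas, stds, constant_mask
        ``lambdas[i]`` for constant columns (``s_i == 0``) is a placeholder
        equal to ``capital_lambda`` and is flagged in ``constant_mask``;
        such features are later forced to ``theta_i = 0``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 samples to estimate stds, got {X.shape[0]}")
    if not (np.isfinite(capital_lambda) and capital_lambda > 0):
        raise ValueError("capital_lambda must be finite and > 0")
    stds = X.std(axis=0, ddof=ddof)
    constant_mask = stds == 0.0
    safe = np.where(constant_mask, 1.0, stds)
    lambdas = capital_lambda / safe**2
    return lambdas, stds, constant_mask


def _class_index(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted unique classes, per-sample class index, and class sizes."""
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-D")
    classes, idx = np.unique(labels, return_inverse=True)
    sizes = np.bincount(idx, minlength=classes.shape[0])
    return classes, idx, sizes


def estimate_alphas(
    X: np.ndarray,
    labels: np.ndarray,
    lambdas: np.ndarray,
    capital_theta: float = 1.0,
    constant_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature relevance scores from leave-one-out proximity gaps.

    For each feature ``i`` and each training sample ``x`` in class ``k``:

        gap = R_i(x, C_k \\ {x}) / (m_k - 1)  -  R_i(x, C \\ {x}) / (m - 1)

    where ``R_i`` is the single-feature proximity with exponent
    ``capital_theta``.  ``alpha_i`` is the sum of the gaps over all training
    samples, floored at 0.  Requires every class to have at least 2 members.
    """
    X = np.asarray(X, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    m, n = X.shape
    classes, cls_idx, sizes = _class_index(np.asarray(labels))
    if np.any(sizes < 2):
        bad = classes[np.argmin(sizes)]
        raise ValueError(
            f"class {bad!r} has {int(sizes.min())} sample(s); every class needs at least 2"
        )
    if constant_mask is None:
        constant_mask = np.zeros(n, dtype=bool)
    onehot = np.zeros((m, classes.shape[0]))
    onehot[np.arange(m), cls_idx] = 1.0
    mk = sizes[cls_idx].astype(float)  # own-class size per sample

    alphas = np.zeros(n)
    for i in range(n):
        if constant_mask[i]:
            continue
        d = X[:, i][:, None] - X[None, :, i]
        K = np.exp(-capital_theta * np.log1p(lambdas[i] * d * d))  # diag == 1
        within = (K @ onehot)[np.arange(m), cls_idx] - 1.0  # R_i(x, C_k \ {x})
        total = K.sum(axis=1) - 1.0  # R_i(x, C \ {x})
        gaps = within / (mk - 1.0) - total / (m - 1.0)
        alphas[i] = max(0.0, float(gaps.sum()))
    return alphas


def estimate_thetas(
    alphas: np.ndarray,
    capital_theta: float = 1.0,
    constant_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exponents proportional to the relevance scores.

    ``theta_i = n_active * alpha_i * capital_theta / sum(alphas)`` over the
    non-constant features, so the active exponents sum to
    ``n_active * capital_theta``.  If every ``alpha_i`` is zero the exponents
    fall back to the uniform value ``capital_theta``.  Constant features get
    ``theta_i = 0`` and are excluded from the budget.
    """
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0):
        raise ValueError("alphas must be nonnegative")
    n = alphas.shape[0]
    if constant_mask is None:
        constant_mask = np.zeros(n, dtype=bool)
    active = ~np.asarray(constant_mask, dtype=bool)
    n_active = int(active.sum())
    thetas = np.zeros(n)
    if n_active == 0:
        return thetas
    total = float(alphas[active].sum())
    if total > 0:
        thetas[active] = n_active * alphas[active] * capital_theta / total
    else:
        thetas[active] = capital_theta
    return thetas


@dataclass
class LucckModel:
    """A fitted instance-based model: training data plus kernel parameters."""

    training_matrix: np.ndarray
    labels: np.ndarray
    classes: np.ndarray
    class_sizes: np.ndarray
    params: KernelParams
    alphas: np.ndarray
    feature_stds: np.ndarray
    class_weights: np.ndarray | None = None
    feature_names: list[str] | None = None
    std_ddof: int = 0
    _class_members: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._class_members:
            cls_idx = np.searchsorted(self.classes, self.labels)
            self._class_members = [
                np.flatnonzero(cls_idx == k) for k in range(self.classes.shape[0])
            ]

    @property
    def n_features(self) -> int:
        return self.training_matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return self.classes.shape[0]

    # ---- scoring -------------------------------------------------------

    def _log_q(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"query has {X.shape[1]} features, model expects {self.n_features}"
            )
        return log_similarity_matrix(X, self.training_matrix, self.params)

    def class_scores(self, x: np.ndarray) -> np.ndarray:
        """Raw proximity sums ``R(x, C_1) ... R(x, C_d)`` for one query or a batch.

        Each score lies in ``(0, m_k]``; larger classes naturally produce
        larger sums (no per-class normalization).
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        q = np.exp(self._log_q(x))  # (b, m)
        scores = np.stack([q[:, idx].sum(axis=1) for idx in self._class_members], axis=1)
        return scores[0] if single else scores

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities ``p_k = R(x, C_k) / R(x, C)``, reweighted if
        class weights were fitted.

        Computed with a per-row log shift so that distant queries (whose raw
        kernel products underflow) still get well-defined probabilities.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        log_q = self._log_q(x)
        shift = log_q.max(axis=1, keepdims=True)
        q = np.exp(log_q - shift)
        scores = np.stack([q[:, idx].sum(axis=1) for idx in self._class_members], axis=1)
        probs = scores / scores.sum(axis=1, keepdims=True)
        if self.class_weights is not None:
            w = probs * self.class_weights[None, :]
            probs = w / w.sum(axis=1, keepdims=True)
        return probs[0] if single else probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Most probable class label(s); ties broken toward the smallest class id."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        probs = np.atleast_2d(self.predict_proba(x))
        # argmax returns the first (= smallest class, classes are sorted) maximum
        winners = self.classes[np.argmax(probs, axis=1)]
        return winners[0] if single else winners

    def loo_probabilities(self) -> np.ndarray:
        """Leave-one-out class probabilities for every training sample.

        Row ``j`` holds ``R(x_j, C_k \\ {x_j}) / R(x_j, C \\ {x_j})`` for
        every class ``k``; rows sum to 1.  Requires all class sizes >= 2.
        """
        if np.any(self.class_sizes < 2):
            bad = self.classes[np.argmin(self.class_sizes)]
            raise ValueError(f"class {bad!r} has fewer than 2 samples")
        m = self.training_matrix.shape[0]
        q = np.exp(self._log_q(self.training_matrix))  # diag == 1 exactly
        cls_idx = np.searchsorted(self.classes, self.labels)
        scores = np.stack([q[:, idx].sum(axis=1) for idx in self._class_members], axis=1)
        scores[np.arange(m), cls_idx] -= 1.0  # drop self-similarity
        denom = scores.sum(axis=1, keepdims=True)
        if np.any(denom <= 0):  # total underflow: fall back to uniform
            flat = denom[:, 0] <= 0
            scores[flat] = 1.0
            denom = scores.sum(axis=1, keepdims=True)
        return scores / denom

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "training_matrix": self.training_matrix.tolist(),
            "labels": self.labels.tolist(),
            "classes": self.classes.tolist(),
            "class_sizes": self.class_sizes.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "lambdas": self.params.lambdas.tolist(),
            "alphas": self.alphas.tolist(),
            "thetas": self.params.thetas.tolist(),
            "capital_lambda": self.params.capital_lambda,
            "capital_theta": self.params.capital_theta,
            "constant_mask": (
                self.params.constant_mask.tolist()
                if self.params.constant_mask is not None
                else None
            ),
            "class_weights": (
                self.class_weights.tolist() if self.class_weights is not None else None
            ),
            "feature_names": self.feature_names,
            "std_ddof": self.std_ddof,
        }

    def save(self, path: str | Path) -> None:
        """Write the model as a single JSON document.

        Python's JSON writer emits the shortest decimal string that
        round-trips each binary64 value, so save/load is lossless.
        """
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "LucckModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')!r}")
        params = KernelParams(
            lambdas=np.array(d["lambdas"], dtype=float),
            thetas=np.array(d["thetas"], dtype=float),
            capital_lambda=float(d["capital_lambda"]),
            capital_theta=float(d["capital_theta"]),
            constant_mask=(
                np.array(d["constant_mask"], dtype=bool)
                if d.get("constant_mask") is not None
                else None
            ),
        )
        weights = d.get("class_weights")
        return cls(
            training_matrix=np.array(d["training_matrix"], dtype=float),
            labels=np.array(d["labels"]),
            classes=np.array(d["classes"]),
            class_sizes=np.array(d["class_sizes"], dtype=int),
            params=params,
            alphas=np.array(d["alphas"], dtype=float),
            feature_stds=np.array(d["feature_stds"], dtype=float),
            class_weights=np.array(weights, dtype=float) if weights is not None else None,
            feature_names=d.get("feature_names"),
            std_ddof=int(d.get("std_ddof", 0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LucckModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(
    X: np.ndarray,
    labels: np.ndarray,
    capital_lambda: float = 1.0,
    capital_theta: float = 1.0,
    reweight: bool = False,
    std_ddof: int = 0,
    feature_names: list[str] | None = None,
    omega_max: float = 100.0,
) -> LucckModel:
    """Fit a model: estimate length scales, relevance scores, and exponents.

    Parameters
    ----------
    X : ndarray of shape (m, n)
        Training feature matrix (finite values).
    labels : array-like of shape (m,)
        Class labels; at least 2 classes, each with at least 2 members.
    capital_lambda, capital_theta : float
        Global hyperparameters (kernel width scale and exponent budget).
    reweight : bool
        If true, fit class weights by linear programming from the
        leave-one-out probability table.
    std_ddof : int
        Standard-deviation convention (0 = population, 1 = sample).
    omega_max : float
        Upper bound on the class weights in the reweighting LP.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match number of rows in X")
    classes, _, sizes = _class_index(labels)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if np.any(sizes < 2):
        bad = classes[np.argmin(sizes)]
        raise ValueError(f"class {bad!r} has fewer than 2 samples")

    lambdas, stds, constant_mask = estimate_lambdas(X, capital_lambda, ddof=std_ddof)
    alphas = estimate_alphas(X, labels, lambdas, capital_theta, constant_mask)
    thetas = estimate_thetas(alphas, capital_theta, constant_mask)
    params = KernelParams(
        lambdas=lambdas,
        thetas=thetas,
        capital_lambda=capital_lambda,
        capital_theta=capital_theta,
        constant_mask=constant_mask,
    )
    model = LucckModel(
        training_matrix=X,
        labels=labels,
        classes=classes,
        class_sizes=sizes,
        params=params,
        alphas=alphas,
        feature_stds=stds,
        feature_names=list(feature_names) if feature_names is not None else None,
        std_ddof=std_ddof,
    )
    if reweight:
        from .reweighting import fit_weights

        table = model.loo_probabilities()
        cls_idx = np.searchsorted(classes, labels)
        model.class_weights = fit_weights(table, cls_idx, omega_max=omega_max)
    return model
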