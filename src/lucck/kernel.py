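"""Per-feature similarity kernels and proximity sums.

The elementary kernel is ``q(x) = (1 + lam * x**2) ** (-theta)``: an even,
strictly positive function of a scalar feature difference, equal to 1 at the
origin and decaying polynomially (a "fat tail") rather than exponentially.
The multivariate similarity of two feature vectors is the product of the
per-feature kernels, and the proximity of a point to a set of reference
vectors is the sum of its similarities to the members of that set.

Products over many features underflow in double precision, so all
multivariate evaluations go through log space:
``Q(x - y) = exp(-sum_i theta_i * log1p(lam_i * (x_i - y_i)**2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams",
    "kernel_value",
    "similarity",
    "proximity",
    "single_feature_proximity",
    "log_similarity_matrix",
]

_SUM_RTOL = 1e-9


@dataclass(frozen=True)
class KernelParams:
    """Complete parameterization of the product similarity kernel.

    Attributes
    ----------
    lambdas : ndarray of shape (n,)
        Per-feature inverse-square length scales, all strictly positive.
    thetas : ndarray of shape (n,)
        Per-feature exponents, all nonnegative.  A feature with
        ``theta_i == 0`` contributes a constant factor 1 (it is ignored).
    capital_lambda : float
        Global scale hyperparameter used to derive ``lambdas`` from feature
        standard deviations (``lam_i = capital_lambda / s_i**2``).
    capital_theta : float
        Global exponent budget: when the exponents are data-driven they sum
        to ``n_active * capital_theta`` over the non-constant features.
    """

    lambdas: np.ndarray
    thetas: np.ndarray
    capital_lambda: float = 1.0
    capital_theta: float = 1.0
    # features excluded from the exponent budget (constant columns)
    constant_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        lambdas = np.asarray(self.lambdas, dtype=float)
        thetas = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "lambdas", lambdas)
        object.__setattr__(self, "thetas", thetas)
        if lambdas.ndim != 1 or thetas.ndim != 1:
            raise ValueError("lambdas and thetas must be 1-D arrays")
        if lambdas.shape != thetas.shape:
            raise ValueError(
                f"lambdas and thetas length mismatch: {lambdas.shape[0]} != {thetas.shape[0]}"
            )
        if not np.all(np.isfinite(lambdas)) or np.any(lambdas <= 0):
            raise ValueError("all lambdas must be finite and > 0")
        if not np.all(np.isfinite(thetas)) or np.any(thetas < 0):
            raise ValueError("all thetas must be finite and >= 0")
        if not (np.isfinite(self.capital_lambda) and self.capital_lambda > 0):
            raise ValueError("capital_lambda must be finite and > 0")
        if not (np.isfinite(self.capital_theta) and self.capital_theta > 0):
            raise ValueError("capital_theta must be finite and > 0")
        if self.constant_mask is not None:
            mask = np.asarray(self.constant_mask, dtype=bool)
            if mask.shape != lambdas.shape:
                raise ValueError("constant_mask length mismatch")
            object.__setattr__(self, "constant_mask", mask)

    @property
    def n_features(self) -> int:
        return self.lambdas.shape[0]


def kernel_value(x: float, lam: float, theta: float) -> float:
    """Evaluate the scalar kernel ``(1 + lam * x**2) ** (-theta)``.

    Parameters
    ----------
    x : float
        Scalar feature difference.
    lam : float
        Positive inverse-square length scale.
    theta : float
        Nonnegative exponent; ``theta == 0`` always yields 1.

    Returns
    -------
    float
        Similarity in ``(0, 1]``; equals 1 iff ``x == 0`` or ``theta == 0``.
    """
    if not np.isfinite(x):
        raise ValueError(f"x must be finite, got {x}")
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be finite and > 0, got {lam}")
    if not (np.isfinite(theta) and theta >= 0):
        raise ValueError(f"theta must be finite and >= 0, got {theta}")
    return float(np.exp(-theta * np.log1p(lam * x * x)))


def _check_vector(x: np.ndarray, n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != n:
        raise ValueError(f"{name} must be a length-{n} vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def similarity(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """Product similarity ``Q(x - y) = prod_i (1 + lam_i (x_i - y_i)^2)^(-theta_i)``.

    Symmetric in ``(x, y)`` and equal to 1 when ``x == y``.
    """
    n = params.n_features
    x = _check_vector(x, n, "x")
    y = _check_vector(y, n, "y")
    d = x - y
    return float(np.exp(-np.dot(params.thetas, np.log1p(params.lambdas * d * d))))


def _check_matrix(Y: np.ndarray, n: int) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1) if n == 1 else Y.reshape(1, -1)
    if Y.ndim != 2 or Y.shape[1] != n:
        raise ValueError(f"Y must be a 2-D array with {n} columns, got shape {Y.shape}")
    if Y.shape[0] == 0:
        raise ValueError("Y must contain at least one row")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    return Y


def proximity(x: np.ndarray, Y: np.ndarray, params: KernelParams) -> float:
    """Proximity sum ``R(x, Y) = sum_{y in Y} Q(x - y)``.

    Lies in ``(0, |Y|]`` and equals ``|Y|`` iff every row of ``Y`` equals
    ``x`` (or all exponents are zero).
    """
    n = params.n_features
    x = _check_vector(x, n, "x")
    Y = _check_matrix(Y, n)
    d = Y - x  # (m, n)
    log_q = -np.log1p(params.lambdas * d * d) @ params.thetas
    return float(np.exp(log_q).sum())


def single_feature_proximity(
    x: np.ndarray,
    Y: np.ndarray,
    i: int,
    lam_i: float,
    capital_theta: float,
) -> float:
    """Single-feature proximity ``R_i(x, Y) = sum_y (1 + lam_i (x_i - y_i)^2)^(-Theta)``.

    The exponent is the *global* ``capital_theta``, not a per-feature one:
    this is the quantity the per-feature relevance scores are built from.
    """
    if not (np.isfinite(lam_i) and lam_i > 0):
        raise ValueError(f"lam_i must be finite and > 0, got {lam_i}")
    if not (np.isfinite(capital_theta) and capital_theta > 0):
        raise ValueError(f"capital_theta must be finite and > 0, got {capital_theta}")
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if Y.shape[0] == 0:
        raise ValueError("Y must contain at least one row")
    if not (0 <= i < Y.shape[1]):
        raise ValueError(f"feature index {i} out of range for {Y.shape[1]} features")
    xi = float(x.reshape(-1)[i]) if x.ndim else float(x)
    d = Y[:, i] - xi
    return float(np.exp(-capital_theta * np.log1p(lam_i * d * d)).sum())


def log_similarity_matrix(X: np.ndarray, Y: np.ndarray, params: KernelParams) -> np.ndarray:
    """Log-similarities between every row of ``X`` and every row of ``Y``.

    Returns the ``(len(X), len(Y))`` matrix of ``log Q(x - y)``, computed
    feature by feature to bound memory at O(m * m') per feature.
    """
    n = params.n_features
    X = _check_matrix(X, n)
    Y = _check_matrix(Y, n)
    out = np.zeros((X.shape[0], Y.shape[0]))
    for i in range(n):
        th = params.thetas[i]
        if th == 0.0:
            continue
        d = X[:, i][:, None] - Y[None, :, i]
        out -= th * np.log1p(params.lambdas[i] * d * d)
    return out
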