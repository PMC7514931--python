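"""Class reweighting via linear programming.

When one class soaks up a disproportionate share of predictions, the output
probability vectors can be post-hoc reweighted by per-class multipliers
``omega_k >= 1``:

    W_omega(p)_l = omega_l * p_l / sum_k omega_k * p_k.

Good multipliers are learned from the leave-one-out probability table of the
training set by minimizing a linear surrogate of the total misclassification:

    sum_j max_k { omega_k * ptilde_k(x_j) }  -  sum_k omega_k * sum_{x in C_k} ptilde_k(x)

which becomes an LP after introducing one auxiliary variable per row for the
max term.  The exact (nonlinear) misclassification measure, which keeps the
normalizing denominator, is available as a diagnostic only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "apply_weights",
    "surrogate_objective",
    "fit_weights",
    "misclassification_measure",
]


def apply_weights(p: np.ndarray, omegas: np.ndarray) -> np.ndarray:
    """Reweight a probability vector (or a batch of rows) by class multipliers."""
    p = np.asarray(p, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    if p.shape[-1] != omegas.shape[0]:
        raise ValueError(
            f"length mismatch: probabilities have {p.shape[-1]} classes, weights {omegas.shape[0]}"
        )
    w = p * omegas
    denom = w.sum(axis=-1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("reweighting denominator is zero")
    return w / denom


def _check_table(table: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if table.ndim != 2:
        raise ValueError("probability table must be 2-D (samples x classes)")
    if labels.shape[0] != table.shape[0]:
        raise ValueError("labels length must match table rows")
    if np.any(table < 0):
        raise ValueError("probability table has negative entries")
    d = table.shape[1]
    if np.any((labels < 0) | (labels >= d)):
        raise ValueError(f"labels must be class indices in [0, {d})")
    return table, labels


def surrogate_objective(table: np.ndarray, labels: np.ndarray, omegas: np.ndarray) -> float:
    """Linear surrogate misclassification for a leave-one-out table.

    ``sum_j max_k(omega_k * p_jk) - sum_j omega_{y_j} * p_{j,y_j}``; always
    nonnegative because the row max dominates the own-class term.
    """
    table, labels = _check_table(table, labels)
    omegas = np.asarray(omegas, dtype=float)
    weighted = table * omegas[None, :]
    return float(weighted.max(axis=1).sum() - weighted[np.arange(len(labels)), labels].sum())


def misclassification_measure(table: np.ndarray, labels: np.ndarray, omegas: np.ndarray) -> float:
    """Exact (normalized) misclassification: ``sum_j max_k p'_jk - p'_{j,y_j}``.

    Diagnostic only — this is the nonlinear quantity the LP surrogate stands
    in for; it is never optimized directly.
    """
    table, labels = _check_table(table, labels)
    reweighted = apply_weights(table, np.asarray(omegas, dtype=float))
    return float(
        reweighted.max(axis=1).sum() - reweighted[np.arange(len(labels)), labels].sum()
    )


def fit_weights(
    table: np.ndarray,
    labels: np.ndarray,
    omega_max: float = 100.0,
) -> np.ndarray:
    """Learn class weights by solving the surrogate LP.

    Variables are ``(omega_1..omega_d, z_1..z_m)``; the LP is

        minimize    sum_j z_j - sum_k omega_k * S_k,   S_k = sum_{j in C_k} p_jk
        subject to  z_j >= omega_k * p_jk   for every row j and class k,
                    1 <= omega_k <= omega_max.

    The box upper bound keeps the solver away from unbounded scaling
    directions of objective-0 faces.  Returns the optimal ``omega``.
    """
    table, labels = _check_table(table, labels)
    m, d = table.shape
    if d == 1:
        return np.ones(1)
    if m == 0:
        return np.ones(d)

    own = np.zeros(d)
    for k in range(d):
        own[k] = table[labels == k, k].sum()
    c = np.concatenate([-own, np.ones(m)])

    # constraint rows: omega_k * p_jk - z_j <= 0
    rows = np.repeat(np.arange(m), d)
    cols_omega = np.tile(np.arange(d), m)
    A = np.zeros((m * d, d + m))
    A[np.arange(m * d), cols_omega] = table[rows, cols_omega]
    A[np.arange(m * d), d + rows] = -1.0
    b = np.zeros(m * d)

    bounds = [(1.0, omega_max)] * d + [(0.0, None)] * m
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"reweighting LP failed: {res.status} ({res.message})")
    return np.asarray(res.x[:d], dtype=float)
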