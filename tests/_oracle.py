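"""Literal, unoptimized reference implementations used only by the tests.

Everything here is written with plain Python loops and scalar math, straight
from the defining formulas, and stays independent of the package's vectorized
code paths.
"""

from __future__ import annotations

import math


def oracle_std(col, ddof=0):
    m = len(col)
    mean = sum(col) / m
    return math.sqrt(sum((v - mean) ** 2 for v in col) / (m - ddof))


def oracle_kernel(diff, lam, theta):
    return (1.0 + lam * diff * diff) ** (-theta)


def oracle_similarity(x, y, lambdas, thetas):
    out = 1.0
    for xi, yi, lam, th in zip(x, y, lambdas, thetas):
        out *= oracle_kernel(xi - yi, lam, th)
    return out


def oracle_proximity(x, Y, lambdas, thetas):
    return sum(oracle_similarity(x, y, lambdas, thetas) for y in Y)


def oracle_single_feature_proximity(x, Y, i, lam_i, capital_theta):
    return sum(oracle_kernel(x[i] - y[i], lam_i, capital_theta) for y in Y)


def oracle_fit(X, labels, capital_lambda=1.0, capital_theta=1.0, ddof=0):
    """Closed-form parameter estimation, transcribed term by term.

    Returns (stds, lambdas, alphas, thetas) as plain lists.  Constant
    features get a placeholder lambda and theta = 0, and are excluded from
    the exponent budget.
    """
    X = [list(map(float, row)) for row in X]
    labels = list(labels)
    m, n = len(X), len(X[0])
    classes = sorted(set(labels))
    members = {k: [j for j, l in enumerate(labels) if l == k] for k in classes}

    stds = [oracle_std([X[j][i] for j in range(m)], ddof) for i in range(n)]
    lambdas = [capital_lambda / s**2 if s > 0 else capital_lambda for s in stds]
    constant = [s == 0 for s in stds]

    alphas = []
    for i in range(n):
        if constant[i]:
            alphas.append(0.0)
            continue
        total = 0.0
        for k in classes:
            mk = len(members[k])
            for j in members[k]:
                r_class = sum(
                    oracle_kernel(X[j][i] - X[j2][i], lambdas[i], capital_theta)
                    for j2 in members[k] if j2 != j
                )
                r_all = sum(
                    oracle_kernel(X[j][i] - X[j2][i], lambdas[i], capital_theta)
                    for j2 in range(m) if j2 != j
                )
                total += r_class / (mk - 1) - r_all / (m - 1)
        alphas.append(max(0.0, total))

    active = [i for i in range(n) if not constant[i]]
    n_active = len(active)
    alpha_sum = sum(alphas[i] for i in active)
    thetas = [0.0] * n
    for i in active:
        if alpha_sum > 0:
            thetas[i] = n_active * alphas[i] * capital_theta / alpha_sum
        else:
            thetas[i] = capital_theta
    return stds, lambdas, alphas, thetas


def oracle_class_scores(X, labels, lambdas, thetas, x):
    classes = sorted(set(labels))
    return [
        sum(
            oracle_similarity(x, X[j], lambdas, thetas)
            for j in range(len(X)) if labels[j] == k
        )
        for k in classes
    ]


def oracle_predict_proba(X, labels, lambdas, thetas, x):
    scores = oracle_class_scores(X, labels, lambdas, thetas, x)
    total = sum(scores)
    return [s / total for s in scores]


def oracle_predict(X, labels, lambdas, thetas, x):
    classes = sorted(set(labels))
    scores = oracle_class_scores(X, labels, lambdas, thetas, x)
    best = max(scores)
    for k, s in zip(classes, scores):  # smallest class wins ties
        if s == best:
            return k
    raise AssertionError


def oracle_loo_table(X, labels, lambdas, thetas):
    classes = sorted(set(labels))
    m = len(X)
    table = []
    for j in range(m):
        row = []
        for k in classes:
            row.append(sum(
                oracle_similarity(X[j], X[j2], lambdas, thetas)
                for j2 in range(m) if j2 != j and labels[j2] == k
            ))
        total = sum(row)
        table.append([v / total for v in row])
    return table


def oracle_dft_features(samples, fs):
    """O(N^2) discrete-Fourier transcription of the six spectral features."""
    n = len(samples)
    mean = sum(samples) / n
    x = [v - mean for v in samples]
    n_bins = n // 2
    freqs, amps = [], []
    for k in range(1, n_bins + 1):
        re = sum(x[t] * math.cos(-2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(-2 * math.pi * k * t / n) for t in range(n))
        mag = math.hypot(re, im)
        scale = 1.0 / n if (n % 2 == 0 and k == n_bins) else 2.0 / n
        freqs.append(k * fs / n)
        amps.append(mag * scale)
    peak = max(range(len(amps)), key=lambda k: amps[k])
    srt = sorted(amps)
    mid = len(srt) // 2
    median = srt[mid] if len(srt) % 2 else 0.5 * (srt[mid - 1] + srt[mid])
    total_amp = sum(amps)
    return {
        "peak_freq": freqs[peak],
        "peak_amp": amps[peak],
        "fft_power": sum(a * a for a in amps),
        "mean_fft_amp": total_amp / len(amps),
        "mean_fft_freq": (
            sum(f * a for f, a in zip(freqs, amps)) / total_amp if total_amp > 0 else 0.0
        ),
        "median_fft_amp": median,
    }


def oracle_grid_weights(table, labels, omega_max, step=0.1):
    """Exhaustive grid search over omega in {1, 1+step, ..., omega_max}^d."""
    import itertools

    m = len(table)
    d = len(table[0])
    values = []
    v = 1.0
    while v <= omega_max + 1e-12:
        values.append(round(v, 10))
        v += step

    def objective(omega):
        tot = 0.0
        for j in range(m):
            weighted = [omega[k] * table[j][k] for k in range(d)]
            tot += max(weighted) - weighted[labels[j]]
        return tot

    best_obj, best_omega = math.inf, None
    for omega in itertools.product(values, repeat=d):
        obj = objective(omega)
        if obj < best_obj:
            best_obj, best_omega = obj, omega
    return best_obj, best_omega
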