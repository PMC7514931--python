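"""Synthetic labeled tabular data with the structure the classifier targets.

Generates class-separated feature matrices with either Gaussian or
heavy-tailed (Student-t) per-feature noise, a controllable number of
informative features, sporadic large single-feature corruptions, grouped
samples (subjects), and controllable class imbalance.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SimulationConfig", "generate", "generate_imbalanced"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the generator.

    ``separation`` is the spacing of adjacent class means on each
    informative feature, in units of ``noise_scale``.  ``corruption_rate``
    is the probability that a sample has exactly one uniformly chosen
    feature replaced by ``class_mean ± corruption_scale * noise_scale``.
    Heavy-tailed noise is Student-t with ``tail_df`` degrees of freedom
    (df=1 is Cauchy).  Groups are assigned round-robin within each class;
    ``group_effect`` adds a shared per-(group, feature) offset.
    """

    n_features: int = 6
    n_informative: int = 3
    class_counts: tuple[int, ...] = (50, 50)
    separation: float = 2.0
    noise: str = "gaussian"  # or "heavy_tailed"
    tail_df: float = 2.0
    noise_scale: float = 1.0
    corruption_rate: float = 0.0
    corruption_scale: float = 20.0
    group_count: int = 10
    group_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or not (0 <= self.n_informative <= self.n_features):
            raise ValueError("need 0 <= n_informative <= n_features and n_features >= 1")
        if len(self.class_counts) < 1 or any(c < 2 for c in self.class_counts):
            raise ValueError("every class needs at least 2 samples")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        if self.noise not in ("gaussian", "heavy_tailed"):
            raise ValueError(f"unknown noise family {self.noise!r}")
        if self.noise == "heavy_tailed" and self.tail_df <= 0:
            raise ValueError("tail_df must be > 0")
        if self.noise_scale <= 0 or self.corruption_scale < 0:
            raise ValueError("noise_scale must be > 0 and corruption_scale >= 0")
        if self.group_count < 1:
            raise ValueError("group_count must be >= 1")


def generate(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a labeled grouped feature matrix.

    Returns ``(X, labels, groups)`` with labels ``1..d`` and group ids
    ``0..group_count-1``.  Informative features of class ``k`` are centered
    at ``(k-1) * separation * noise_scale``; non-informative features are
    identically distributed across classes (centered at 0).
    """
    rng = np.random.default_rng(config.seed)
    d = len(config.class_counts)
    m = int(sum(config.class_counts))
    n = config.n_features

    labels = np.concatenate(
        [np.full(c, k + 1, dtype=int) for k, c in enumerate(config.class_counts)]
    )
    groups = np.concatenate(
        [np.arange(c) % config.group_count for c in config.class_counts]
    )

    if config.noise == "gaussian":
        noise = rng.standard_normal((m, n))
    else:
        noise = rng.standard_t(config.tail_df, size=(m, n))
    X = noise * config.noise_scale

    means = np.zeros((m, n))
    means[:, : config.n_informative] = (
        (labels[:, None] - 1) * config.separation * config.noise_scale
    )
    X += means

    if config.group_effect > 0:
        offsets = rng.standard_normal((config.group_count, n)) * (
            config.group_effect * config.noise_scale
        )
        X += offsets[groups]

    if config.corruption_rate > 0:
        hit = rng.random(m) < config.corruption_rate
        feat = rng.integers(0, n, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        idx = np.flatnonzero(hit)
        X[idx, feat[idx]] = (
            means[idx, feat[idx]]
            + sign[idx] * config.corruption_scale * config.noise_scale
        )

    return X, labels, groups


def generate_imbalanced(
    config: SimulationConfig, ratio: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class draw with minority/majority class counts in ``ratio``.

    The majority count is taken from ``config.class_counts[0]``; the
    minority count is ``round(ratio * majority)`` (at least 2).
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    majority = int(config.class_counts[0])
    minority = max(2, int(round(ratio * majority)))
    cfg = replace(config, class_counts=(majority, minority))
    return generate(cfg)
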