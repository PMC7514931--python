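"""CSV input/output for feature tables and signal windows."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signal_features import SignalWindow

__all__ = ["load_feature_table", "write_feature_table", "read_signal_csv"]


def load_feature_table(
    path: str | Path,
    label_column: str | None = None,
    group_column: str | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, list[str]]:
    """Read a headered feature CSV into ``(X, labels, groups, feature_names)``.

    Every column other than the label/group columns must be numeric and
    complete; missing values are rejected with a clear error.
    """
    df = pd.read_csv(path)
    if label_column is not None and label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    if group_column is not None and group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path}")
    labels = df[label_column].to_numpy() if label_column else None
    groups = df[group_column].to_numpy() if group_column else None
    feature_cols = [c for c in df.columns if c not in (label_column, group_column)]
    features = df[feature_cols]
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValueError(f"missing values in feature column(s) {bad} of {path}")
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature column in {path}: {exc}") from exc
    if labels is not None and pd.isna(labels).any():
        raise ValueError(f"missing values in label column {label_column!r} of {path}")
    return X, labels, groups, feature_cols


def write_feature_table(
    path: str | Path,
    X: np.ndarray,
    feature_names: list[str],
    labels: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    label_column: str = "label",
    group_column: str = "group",
) -> None:
    """Write features (plus optional label/group columns) as a headered CSV."""
    df = pd.DataFrame(np.asarray(X), columns=feature_names)
    if labels is not None:
        df[label_column] = labels
    if groups is not None:
        df[group_column] = groups
    df.to_csv(path, index=False)


def read_signal_csv(
    path: str | Path,
    sampling_rate: float,
    value_column: str | None = None,
) -> SignalWindow:
    """Read a single-channel time series CSV into a window.

    With one column the values are taken directly; with several,
    ``value_column`` selects the channel (a ``timestamp``/``time`` column,
    if present, is ignored — sampling is assumed uniform at
    ``sampling_rate``).
    """
    df = pd.read_csv(path)
    if value_column is not None:
        if value_column not in df.columns:
            raise ValueError(f"value column {value_column!r} not found in {path}")
        values = df[value_column]
    elif df.shape[1] == 1:
        values = df.iloc[:, 0]
    else:
        candidates = [c for c in df.columns if c.lower() not in ("timestamp", "time", "t")]
        if len(candidates) != 1:
            raise ValueError(
                f"{path} has {df.shape[1]} columns; pass value_column to pick one"
            )
        values = df[candidates[0]]
    return SignalWindow(values.to_numpy(dtype=float), sampling_rate)
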