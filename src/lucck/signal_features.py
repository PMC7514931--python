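"""Generic statistical and spectral features for uniformly sampled windows.

Conventions (fixed so that features are bit-reproducible):

* "power" is the mean of the squared samples — length-invariant, so windows
  of different durations stay comparable;
* standard deviation / variance use the population convention (divide by N);
* the spectrum is the one-sided amplitude spectrum of the mean-removed
  signal, no taper, amplitudes scaled by 2/N (the Nyquist bin, present for
  even N, by 1/N); the DC bin is excluded from every spectral feature;
* "mean frequency" is the amplitude-weighted mean of the bin frequencies
  (the spectral centroid);
* even-length medians average the two middle order statistics.

Documented spectral identity (asserted in the test suite): with amplitudes
``a_k`` as above, the population variance of the window equals
``sum_k w_k * a_k**2`` where ``w_k = 1/2`` for interior bins and ``1`` for
the Nyquist bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignalWindow",
    "basic_stats",
    "spectral_features",
    "range_stats",
    "amplitude_spectrum",
    "extract_table",
    "FEATURE_BUNDLES",
]

logger = logging.getLogger(__name__)

BASIC_FEATURES = ("mean", "std", "var", "power", "median")
SPECTRAL_FEATURES = (
    "peak_freq",
    "peak_amp",
    "fft_power",
    "mean_fft_amp",
    "mean_fft_freq",
    "median_fft_amp",
)
RANGE_FEATURES = ("max", "min", "range", "mean", "std", "power")

FEATURE_BUNDLES = {
    "basic": BASIC_FEATURES,
    "spectral": SPECTRAL_FEATURES,
    "range": RANGE_FEATURES,
}


@dataclass(frozen=True)
class SignalWindow:
    """A uniformly sampled scalar time series with its sampling rate in Hz."""

    samples: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.shape[0] < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise ValueError("sampling_rate must be finite and > 0")

    def __len__(self) -> int:
        return self.samples.shape[0]


def basic_stats(w: SignalWindow) -> dict[str, float]:
    """Mean, population std, variance, mean-square power, and median."""
    x = w.samples
    std = float(x.std())
    return {
        "mean": float(x.mean()),
        "std": std,
        "var": std * std,
        "power": float(np.mean(x * x)),
        "median": float(np.median(x)),
    }


def range_stats(w: SignalWindow) -> dict[str, float]:
    """Max, min, range, mean, population std, and mean-square power."""
    x = w.samples
    hi, lo = float(x.max()), float(x.min())
    return {
        "max": hi,
        "min": lo,
        "range": hi - lo,
        "mean": float(x.mean()),
        "std": float(x.std()),
        "power": float(np.mean(x * x)),
    }


def amplitude_spectrum(w: SignalWindow) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the mean-removed window, DC excluded.

    Returns ``(freqs_hz, amplitudes)``: interior bins carry ``2|X_k|/N``,
    the Nyquist bin (even N only) ``|X_k|/N``.
    """
    x = w.samples - w.samples.mean()
    n = x.shape[0]
    spectrum = np.fft.rfft(x)
    amps = np.abs(spectrum) * (2.0 / n)
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / w.sampling_rate)
    return freqs[1:], amps[1:]


def spectral_features(w: SignalWindow) -> dict[str, float]:
    """Six spectral features of the one-sided amplitude spectrum.

    Peak frequency and amplitude, total spectral power (sum of squared
    amplitudes), mean amplitude, amplitude-weighted mean frequency
    (spectral centroid; 0 for an identically-zero spectrum), and median
    amplitude.  Requires at least 4 samples.
    """
    if len(w) < 4:
        raise ValueError(f"spectral features need >= 4 samples, got {len(w)}")
    freqs, amps = amplitude_spectrum(w)
    peak = int(np.argmax(amps))
    total_amp = float(amps.sum())
    centroid = float(np.dot(freqs, amps) / total_amp) if total_amp > 0 else 0.0
    return {
        "peak_freq": float(freqs[peak]),
        "peak_amp": float(amps[peak]),
        "fft_power": float(np.dot(amps, amps)),
        "mean_fft_amp": float(amps.mean()),
        "mean_fft_freq": centroid,
        "median_fft_amp": float(np.median(amps)),
    }


_BUNDLE_FUNCS = {
    "basic": basic_stats,
    "spectral": spectral_features,
    "range": range_stats,
}


def extract_table(
    window_sets: list[dict[str, SignalWindow]],
    recipe: dict[str, list[str]],
) -> pd.DataFrame:
    """Build a feature table from per-signal windows.

    Parameters
    ----------
    window_sets : list of dict
        One entry per output row, mapping signal name to its window.
    recipe : dict
        Signal name -> list of bundle names (``"basic"``, ``"spectral"``,
        ``"range"``) to extract from that signal.

    Returns
    -------
    pandas.DataFrame
        One row per valid window set (indexed by its original position),
        columns named ``<signal>.<feature>`` in deterministic recipe order.
        Window sets with a missing signal or a non-finite feature are
        excluded and logged.
    """
    columns: list[str] = []
    for signal, bundles in recipe.items():
        for bundle in bundles:
            if bundle not in _BUNDLE_FUNCS:
                raise ValueError(
                    f"unknown feature bundle {bundle!r}; choose from {sorted(_BUNDLE_FUNCS)}"
                )
            columns.extend(f"{signal}.{name}" for name in FEATURE_BUNDLES[bundle])

    rows: list[list[float]] = []
    kept: list[int] = []
    for j, windows in enumerate(window_sets):
        row: list[float] = []
        ok = True
        for signal, bundles in recipe.items():
            if signal not in windows:
                logger.warning("window set %d: missing signal %r; row excluded", j, signal)
                ok = False
                break
            for bundle in bundles:
                feats = _BUNDLE_FUNCS[bundle](windows[signal])
                row.extend(feats[name] for name in FEATURE_BUNDLES[bundle])
        if ok and not all(np.isfinite(v) for v in row):
            logger.warning("window set %d: non-finite feature value; row excluded", j)
            ok = False
        if ok:
            rows.append(row)
            kept.append(j)
    return pd.DataFrame(rows, columns=columns, index=kept)
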