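"""Twelve time-domain features (f1-f12) computed per 0.5-s EEG window.

The set mixes amplitude statistics (max, mean, std, skewness, kurtosis),
waveform-shape ratios (shape/crest/impulse/margin factors — the latter three
with peak-to-peak numerators), short energy, zero-crossing rate, and the
time centroid.  A k-complex raises the window's amplitude extremes and short
energy and shifts the centroid, which is what makes these separable features.

All formulas are evaluated verbatim:

* std uses the N-1 denominator; skewness/kurtosis are plain moment ratios
  of the standardized signal with that std as scale (kurtosis is NOT excess).
* crest/impulse/margin factors use ``max - min`` in the numerator.
* zero-crossing rate counts sign changes with sgn(0) = +1, divided by N.
* time centroid is 1-based: sum(n * x_n) / sum(x_n).

Degenerate windows (zero std, zero sum) yield 0 for the affected features
with a flag, so downstream feature matrices stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TIME_FEATURE_NAMES = [
    "f01_max",
    "f02_mean",
    "f03_std",
    "f04_skew",
    "f05_kurt",
    "f06_shape",
    "f07_crest",
    "f08_impulse",
    "f09_margin",
    "f10_energy",
    "f11_zcr",
    "f12_tc",
]


@dataclass(frozen=True)
class TimeFeatureVector:
    f1_max: float
    f2_mean: float
    f3_std: float
    f4_skew: float
    f5_kurt: float
    f6_shape: float
    f7_crest: float
    f8_impulse: float
    f9_margin: float
    f10_energy: float
    f11_zcr: float
    f12_tc: float
    degenerate: frozenset[str] = frozenset()

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.f1_max,
                self.f2_mean,
                self.f3_std,
                self.f4_skew,
                self.f5_kurt,
                self.f6_shape,
                self.f7_crest,
                self.f8_impulse,
                self.f9_margin,
                self.f10_energy,
                self.f11_zcr,
                self.f12_tc,
            ]
        )


def time_features(values: np.ndarray) -> TimeFeatureVector:
    """Evaluate f1-f12 on one window."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("window must contain at least 2 samples")

    flags: set[str] = set()

    f1 = float(np.max(x))
    f2 = float(np.mean(x))
    f3 = float(np.sqrt(np.sum((x - f2) ** 2) / (n - 1)))

    if f3 > 0:
        z = (x - f2) / f3
        f4 = float(np.mean(z**3))
        f5 = float(np.mean(z**4))
    else:
        f4 = f5 = 0.0
        flags.add("std_zero")

    rms = float(np.sqrt(np.mean(x**2)))
    mean_abs = float(np.mean(np.abs(x)))
    ptp = float(np.max(x) - np.min(x))
    if mean_abs > 0:
        f6 = rms / mean_abs
        f8 = ptp / mean_abs
        f9 = ptp / mean_abs**2
    else:
        f6 = f8 = f9 = 0.0
        flags.add("mean_abs_zero")
    f7 = ptp / rms if rms > 0 else 0.0

    f10 = float(np.sum(x**2))

    sgn = np.where(x >= 0, 1.0, -1.0)
    num = 0.5 * float(np.sum(np.abs(np.diff(sgn))))
    f11 = num / n

    total = float(np.sum(x))
    if abs(total) > 0:
        f12 = float(np.sum(np.arange(1, n + 1) * x)) / total
    else:
        f12 = 0.0
        flags.add("sum_zero")

    return TimeFeatureVector(
        f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, frozenset(flags)
    )


def time_feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Vectorized f1-f12 over a (n_windows, N) array; one row per window.

    Identical to row-wise :func:`time_features`, but evaluated with array
    reductions so large segment sets stay fast.
    """
    X = np.asarray(windows, dtype=float)
    n = X.shape[1]
    f1 = X.max(axis=1)
    f2 = X.mean(axis=1)
    f3 = np.sqrt(((X - f2[:, None]) ** 2).sum(axis=1) / (n - 1))
    safe_std = np.where(f3 > 0, f3, 1.0)
    z = (X - f2[:, None]) / safe_std[:, None]
    f4 = np.where(f3 > 0, (z**3).mean(axis=1), 0.0)
    f5 = np.where(f3 > 0, (z**4).mean(axis=1), 0.0)
    rms = np.sqrt((X**2).mean(axis=1))
    mean_abs = np.abs(X).mean(axis=1)
    ptp = X.max(axis=1) - X.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f6 = np.where(mean_abs > 0, rms / mean_abs, 0.0)
        f7 = np.where(rms > 0, ptp / rms, 0.0)
        f8 = np.where(mean_abs > 0, ptp / mean_abs, 0.0)
        f9 = np.where(mean_abs > 0, ptp / mean_abs**2, 0.0)
    f10 = (X**2).sum(axis=1)
    sgn = np.where(X >= 0, 1.0, -1.0)
    f11 = 0.5 * np.abs(np.diff(sgn, axis=1)).sum(axis=1) / n
    total = X.sum(axis=1)
    weighted = (np.arange(1, n + 1)[None, :] * X).sum(axis=1)
    f12 = np.where(np.abs(total) > 0, weighted / np.where(total == 0, 1.0, total), 0.0)
    return np.column_stack([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12])
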