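"""Seven spectral features (f13-f19) from a per-window energy spectrum.

The spectrum is the one-sided FFT energy spectrum E(k) = |X(k)|^2 with a
scaling chosen so that Parseval's identity holds exactly:
``sum_k E(k) == sum_n x(n)^2``.  From it the features are

f13  band energy ratio       energy in [f1, f2] band / total (default 0.5-4 Hz,
                             the delta band where k-complex energy lives)
f14  spectral flux           sum_{k>=2} |E(k) - E(k-1)|^2
f15  spectral centroid       energy-weighted mean frequency
f16  bandwidth around f15    energy-weighted mean absolute deviation from f15
f17  spectral flatness       10 log10(geometric mean / arithmetic mean), dB <= 0
f18  spectral roll-off       lowest frequency whose cumulative energy reaches
                             C * total (C default 0.85)
f19  spectral irregularity   sum (E(k)-E(k-1))^2 / sum E(k)^2

A zero spectrum flags the whole vector degenerate and returns zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPECTRAL_FEATURE_NAMES = [
    "f13_ber",
    "f14_flux",
    "f15_sc",
    "f16_bw",
    "f17_sfm",
    "f18_sro",
    "f19_si",
]

_GEOMEAN_FLOOR = 1e-12  # relative epsilon for zero bins in the flatness measure


@dataclass(frozen=True)
class SpectralConfig:
    band: tuple[float, float] = (0.5, 4.0)
    rolloff_c: float = 0.85
    include_dc: bool = True
    hann: bool = False

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not 0 <= lo < hi <= fs / 2:
            raise ValueError(f"band {self.band} outside [0, {fs / 2}]")
        if not 0 < self.rolloff_c <= 1:
            raise ValueError("rolloff_c must be in (0, 1]")


@dataclass(frozen=True)
class PowerSpectrum:
    energies: np.ndarray
    freqs: np.ndarray
    fs: float

    @property
    def total(self) -> float:
        return float(np.sum(self.energies))


@dataclass(frozen=True)
class SpectralFeatureVector:
    f13_ber: float
    f14_flux: float
    f15_sc: float
    f16_bw: float
    f17_sfm: float
    f18_sro: float
    f19_si: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.f13_ber,
                self.f14_flux,
                self.f15_sc,
                self.f16_bw,
                self.f17_sfm,
                self.f18_sro,
                self.f19_si,
            ]
        )


def spectrum(
    values: np.ndarray, fs: float, config: SpectralConfig = SpectralConfig()
) -> PowerSpectrum:
    """One-sided energy spectrum with Parseval-preserving scaling.

    E(k) = |X(k)|^2 / N, doubled for interior bins so the one-sided sum
    equals the full-spectrum sum (DC and Nyquist are not doubled).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    if config.hann:
        x = x * np.hanning(n)
    X = np.fft.rfft(x)
    E = np.abs(X) ** 2 / n
    if n % 2 == 0:
        E[1:-1] *= 2.0  # Nyquist bin present, not doubled
    else:
        E[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    if not config.include_dc:
        E, freqs = E[1:], freqs[1:]
    return PowerSpectrum(energies=E, freqs=freqs, fs=fs)


def spectral_features(
    spec: PowerSpectrum, config: SpectralConfig = SpectralConfig()
) -> SpectralFeatureVector:
    """Evaluate f13-f19 on an energy spectrum."""
    config.validate(spec.fs)
    E = np.asarray(spec.energies, dtype=float)
    f = np.asarray(spec.freqs, dtype=float)
    total = float(np.sum(E))
    if total <= 0:
        return SpectralFeatureVector(0, 0, 0, 0, 0, 0, 0, degenerate=True)

    lo, hi = config.band
    in_band = (f >= lo) & (f <= hi)
    f13 = float(np.sum(E[in_band]) / total)

    dE = np.diff(E)
    f14 = float(np.sum(np.abs(dE) ** 2))

    f15 = float(np.sum(f * E) / total)
    f16 = float(np.sum(np.abs(f15 - f) * E) / total)

    floor = _GEOMEAN_FLOOR * float(np.max(E))
    logE = np.log(np.maximum(E, floor))
    geomean = float(np.exp(np.mean(logE)))
    f17 = float(10.0 * np.log10(geomean / np.mean(E)))

    cum = np.cumsum(E)
    k_ro = int(np.searchsorted(cum, config.rolloff_c * total))
    f18 = float(f[min(k_ro, f.size - 1)])

    f19 = float(np.sum(dE**2) / np.sum(E**2))

    return SpectralFeatureVector(f13, f14, f15, f16, f17, f18, f19)


def spectral_feature_matrix(
    windows: np.ndarray, fs: float, config: SpectralConfig = SpectralConfig()
) -> np.ndarray:
    """f13-f19 for every row of a (n_windows, N) array."""
    rows = [
        spectral_features(spectrum(w, fs, config), config).as_array() for w in windows
    ]
    return np.stack(rows)
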