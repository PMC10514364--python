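"""Synthetic sleep-EEG generator with ground-truth k-complex annotations.

Emulates an N2-like single channel: colored-noise background (an AR(2)
process with its spectral peak in the delta/theta range, band-limited to
0.5-30 Hz) with biphasic k-complex transients superimposed at seeded,
non-overlapping onsets.  The transient follows the AASM verbal morphology —
a well-delineated sharp negative component immediately followed by a slower
positive wave — modeled as two raised-cosine lobes (negative lobe over the
first 40% of the duration, positive over the remaining 60%, amplitude ratio
1.5:1, which balances the lobes to zero net area).  Event durations are
drawn from 0.5-2.0 s.

What this emulates and what it does not: the amplitude asymmetry, duration
range, delta-dominant background, and exact annotations of real N2 sleep
are present; sleep spindles (optional distractors), artifacts, stage
transitions, and inter-subject variability are not.

Fixtures are written in exactly the dialects ``signal_io`` reads: a
standard-header 16-bit EDF plus a plain-text ``onset<TAB>duration``
annotation file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_io import (
    AnnotationSet,
    EEGRecording,
    FilterSpec,
    design_bandpass,
    write_annotations,
)

DURATION_RANGE = (0.5, 2.0)  # admissible k-complex durations, seconds
NEG_FRACTION = 0.4           # fraction of the event occupied by the negative lobe
AMP_RATIO = 1.5              # |negative peak| / positive peak


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of one synthetic recording."""

    fs: float = 200.0
    duration_s: float = 900.0
    n_events: int = 60
    event_duration_range: tuple[float, float] = DURATION_RANGE
    background_sd: float = 15.0     # microvolts
    snr: float = 8.0                # event |negative peak| / background sd
    ar_coeffs: tuple[float, ...] = (1.7, -0.81)  # AR(2), delta-band peak
    spindles: bool = False          # optional 12-14 Hz distractor bursts
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.event_duration_range
        if not (DURATION_RANGE[0] <= lo <= hi <= DURATION_RANGE[1]):
            raise ValueError(f"event durations must lie within {DURATION_RANGE}")
        if self.fs * self.duration_s < self.fs * 0.5:
            raise ValueError("recording shorter than one analysis window")
        if self.n_events < 0 or self.snr < 0:
            raise ValueError("n_events and snr must be non-negative")


def make_kcomplex_waveform(fs: float, duration_s: float, amplitude: float) -> np.ndarray:
    """Biphasic k-complex template: sharp negative lobe then positive wave.

    ``amplitude`` is the magnitude of the negative peak; the positive peak
    is amplitude / 1.5.  The waveform starts and ends at zero and has zero
    net area (the lobe split and amplitude ratio cancel exactly).
    """
    lo, hi = DURATION_RANGE
    if not lo <= duration_s <= hi:
        raise ValueError(f"duration {duration_s} s outside {DURATION_RANGE}")
    n = int(round(duration_s * fs))
    n_neg = int(round(n * NEG_FRACTION))
    n_pos = n - n_neg
    t_neg = np.arange(n_neg) / max(n_neg, 1)
    t_pos = np.arange(n_pos) / max(n_pos, 1)
    neg = -amplitude * 0.5 * (1 - np.cos(2 * np.pi * t_neg))
    pos = (amplitude / AMP_RATIO) * 0.5 * (1 - np.cos(2 * np.pi * t_pos))
    return np.concatenate([neg, pos])


def _background(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded AR colored noise, band-limited to 0.5-30 Hz, unit-sd scaled."""
    n = int(round(spec.fs * spec.duration_s))
    white = rng.standard_normal(n + 2000)  # burn-in to forget initial state
    a = np.concatenate([[1.0], -np.asarray(spec.ar_coeffs)])
    x = sps.lfilter([1.0], a, white)[2000:]
    sos = design_bandpass(FilterSpec(0.5, 30.0, 4), spec.fs)
    x = sps.sosfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _place_events(
    spec: SynthSpec, rng: np.random.Generator, margin_s: float = 0.25
) -> list[tuple[float, float]]:
    """Non-overlapping (onset, duration) pairs, seeded; raises if infeasible."""
    lo, hi = spec.event_duration_range
    durations = rng.uniform(lo, hi, size=spec.n_events)
    needed = float(np.sum(durations + margin_s))
    usable = spec.duration_s - 2 * margin_s
    if needed > usable:
        raise ValueError(
            f"{spec.n_events} events need {needed:.1f} s, recording offers {usable:.1f} s"
        )
    # distribute the free space between events with a seeded Dirichlet-like split
    slack = usable - needed
    gaps = rng.dirichlet(np.ones(spec.n_events + 1)) * slack
    events = []
    cursor = margin_s
    for i, dur in enumerate(durations):
        cursor += gaps[i]
        events.append((float(cursor), float(dur)))
        cursor += dur + margin_s
    return events


def _spindle(fs: float, rng: np.random.Generator) -> np.ndarray:
    dur = rng.uniform(0.5, 1.0)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    freq = rng.uniform(12.0, 14.0)
    return np.hanning(n) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def generate_recording(spec: SynthSpec) -> tuple[EEGRecording, AnnotationSet]:
    """Background plus superimposed k-complexes; identical seed, identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = _background(spec, rng) * spec.background_sd
    events = _place_events(spec, rng)
    x = bg.copy()
    amp = spec.snr * spec.background_sd
    for onset, dur in events:
        i0 = int(round(onset * spec.fs))
        wf = make_kcomplex_waveform(spec.fs, dur, amp)
        end = min(i0 + wf.size, x.size)
        x[i0:end] += wf[: end - i0]
    if spec.spindles:
        n_spindles = max(1, spec.n_events // 3)
        for _ in range(n_spindles):
            sp = _spindle(spec.fs, rng) * spec.background_sd * 2.0
            i0 = rng.integers(0, x.size - sp.size)
            x[i0 : i0 + sp.size] += sp
    recording = EEGRecording(samples=x, fs=spec.fs, channel="Cz-A1")
    annotations = AnnotationSet(events=tuple(events), scorer="synthetic")
    return recording, annotations


# ---------------------------------------------------------------------------
# fixture writing (EDF + annotation text)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: EEGRecording, phys_dim: str = "uV") -> None:
    """Write a minimal standard-header 16-bit EDF file (one data record per
    second).  The recording length must be a whole number of seconds."""
    x = recording.samples
    fs = int(round(recording.fs))
    if abs(recording.fs - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if x.size % fs:
        raise ValueError("EDF writer requires a whole number of seconds")
    nrec = x.size // fs
    pmin, pmax = float(x.min()), float(x.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin).astype("<i2")

    f = _edf_field
    hdr = b"".join(
        [
            f("0", 8),                      # version
            f("X X X X", 80),               # patient id
            f("Startdate X synthetic", 80), # recording id
            f("01.01.20", 8),
            f("00.00.00", 8),
            f(256 * 2, 8),                  # header bytes (1 signal)
            f("", 44),
            f(nrec, 8),
            f("1", 8),                      # record duration, seconds
            f(1, 4),                        # number of signals
            f(recording.channel or "EEG", 16),
            f("AgAgCl electrode", 80),
            f(phys_dim, 8),
            f("%.6g" % pmin, 8),
            f("%.6g" % pmax, 8),
            f(dmin, 8),
            f(dmax, 8),
            f("", 80),                      # prefiltering
            f(fs, 8),                       # samples per record
            f("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(digital.tobytes())


def write_fixture(
    recording: EEGRecording,
    annotations: AnnotationSet,
    out_dir: str | Path,
    stem: str = "synthetic",
) -> tuple[Path, Path]:
    """Emit ``<stem>.edf`` and ``<stem>_annot.txt`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edf_path = out_dir / f"{stem}.edf"
    annot_path = out_dir / f"{stem}_annot.txt"
    write_edf(edf_path, recording)
    write_annotations(annotations, annot_path)
    return edf_path, annot_path
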