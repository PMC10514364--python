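"""EEG input, band-pass filtering, sliding-window segmentation and labeling.

The detection pipeline operates on a single EEG channel (typically Cz-A1,
200 Hz).  The raw signal is band-pass filtered (0.5-30 Hz Butterworth),
cut into short overlapping windows (0.5 s window, 0.1 s step), and each
window is labeled *k-complex* when at least half of its samples fall inside
an expert-annotated event interval.

Conventions
-----------
* Segments are half-open ``[start, start + W)`` in samples, 0-based.
* Annotation intervals are half-open ``[onset, onset + duration)`` in seconds.
* Amplitudes are microvolts throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

log = logging.getLogger("kcomplex")

LABEL_KCOMPLEX = 1
LABEL_NON_KCOMPLEX = 0
LABEL_UNLABELED = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGRecording:
    """A single-channel sampled EEG trace in microvolts."""

    samples: np.ndarray
    fs: float
    channel: str = ""
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class AnnotationSet:
    """Expert-scored event intervals, (onset, duration) pairs in seconds."""

    events: tuple[tuple[float, float], ...]
    scorer: str = "expert1"

    def __post_init__(self) -> None:
        events = tuple((float(o), float(d)) for o, d in self.events)
        for onset, dur in events:
            if onset < 0:
                raise ValueError(f"negative onset {onset}")
            if dur <= 0:
                raise ValueError(f"non-positive duration {dur}")
        if any(events[i][0] > events[i + 1][0] for i in range(len(events) - 1)):
            events = tuple(sorted(events))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification.

    ``order`` is the Butterworth design order, as passed to the design
    routine (the MATLAB/scipy convention: a band-pass of design order N has
    an overall transfer function of order 2N).
    """

    low_hz: float = 0.5
    high_hz: float = 30.0
    order: int = 4
    zero_phase: bool = False

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= fs / 2:
            raise ValueError(f"high edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class Segment:
    """One analysis window with provenance into the source recording."""

    values: np.ndarray
    start_sample: int
    fs: float
    label: int = LABEL_UNLABELED

    @property
    def start_s(self) -> float:
        return self.start_sample / self.fs

    @property
    def end_s(self) -> float:
        return (self.start_sample + len(self.values)) / self.fs


@dataclass
class SegmentSet:
    """An ordered collection of equally sized windows from one recording."""

    segments: list[Segment]
    window_s: float
    step_s: float

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)

    def values_matrix(self) -> np.ndarray:
        """Stack all windows into a (n_segments, N) array."""
        return np.stack([s.values for s in self.segments])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start_sample": [s.start_sample for s in self.segments],
                "start_s": [s.start_s for s in self.segments],
                "label": [s.label for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, channel: str | None = None) -> EEGRecording:
    """Read one channel of an EDF file into an :class:`EEGRecording`.

    Channel matching is case-insensitive. Values are returned in microvolts.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    names = raw.ch_names
    if channel is None:
        idx = 0
    else:
        folded = [n.casefold() for n in names]
        try:
            idx = folded.index(channel.casefold())
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in EDF (available: {names})"
            ) from None
    data = raw.get_data(picks=[idx])[0] * 1e6  # MNE reads volts
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]), channel=names[idx])


def read_annotations(path: str | Path, scorer: str = "expert1") -> AnnotationSet:
    """Parse a plain-text annotation file: one ``onset duration`` pair per line.

    Whitespace- or comma-delimited; ``#`` comments and header lines are
    tolerated, malformed lines are skipped with a warning.
    """
    path = Path(path)
    events: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        parts = text.replace(",", " ").split()
        try:
            onset, dur = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            log.warning("%s:%d: skipping unparsable line %r", path.name, lineno, line)
            continue
        events.append((onset, dur))
    if not events:
        raise ValueError(f"no parsable events in {path}")
    return AnnotationSet(events=tuple(sorted(events)), scorer=scorer)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    lines = ["# onset_s\tduration_s"]
    lines += [f"{o:.4f}\t{d:.4f}" for o, d in annotations.events]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Return the SOS cascade for the Butterworth band-pass of ``spec``."""
    spec.validate(fs)
    return sps.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass_response(spec: FilterSpec, fs: float, freqs_hz: Sequence[float]) -> np.ndarray:
    """Magnitude response of the designed filter at the given frequencies."""
    sos = design_bandpass(spec, fs)
    w, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs_hz, float) / fs)
    return np.abs(h)


def bandpass(recording: EEGRecording, spec: FilterSpec = FilterSpec()) -> EEGRecording:
    """Band-pass filter a recording (causal by default; zero-phase optional)."""
    sos = design_bandpass(spec, recording.fs)
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, recording.samples)
    else:
        out = sps.sosfilt(sos, recording.samples)
    return replace(recording, samples=np.asarray(out, dtype=float))


# ---------------------------------------------------------------------------
# segmentation and labeling
# ---------------------------------------------------------------------------

def _samples(dur_s: float, fs: float, what: str) -> int:
    n = dur_s * fs
    rounded = round(n)
    if rounded <= 0 or abs(n - rounded) > 1e-6:
        raise ValueError(f"{what} ({dur_s} s) must round to a positive sample count at fs={fs}")
    return int(rounded)


def segment(
    recording: EEGRecording, window_s: float = 0.5, step_s: float = 0.1
) -> SegmentSet:
    """Cut the recording into overlapping windows, left to right.

    Produces ``floor((N_total - W) / S) + 1`` windows of W = window_s*fs
    samples at stride S = step_s*fs.
    """
    W = _samples(window_s, recording.fs, "window")
    S = _samples(step_s, recording.fs, "step")
    n_total = recording.samples.size
    if n_total < W:
        raise ValueError(f"recording ({n_total} samples) shorter than one window ({W})")
    count = (n_total - W) // S + 1
    segments = [
        Segment(
            values=recording.samples[i * S : i * S + W],
            start_sample=i * S,
            fs=recording.fs,
        )
        for i in range(count)
    ]
    return SegmentSet(segments=segments, window_s=window_s, step_s=step_s)


def label_segments(
    segments: SegmentSet, annotations: AnnotationSet, min_overlap: float = 0.5
) -> SegmentSet:
    """Label each window by its fractional overlap with annotated events.

    A window is *k-complex* iff the fraction of its duration inside any
    single annotated event is >= ``min_overlap``; both windows and events
    are half-open intervals.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    intervals = [(o, o + d) for o, d in annotations.events]
    for seg in segments:
        a, b = seg.start_s, seg.end_s
        width = b - a
        frac = 0.0
        for lo, hi in intervals:
            if lo >= b:
                break
            overlap = min(b, hi) - max(a, lo)
            if overlap > 0:
                frac = max(frac, overlap / width)
        seg.label = LABEL_KCOMPLEX if frac >= min_overlap else LABEL_NON_KCOMPLEX
    return segments
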