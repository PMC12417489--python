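"""Deterministic signal standardization from raw recordings to model-ready windows.

The chain is: channel selection on a 21-electrode 10-20 montage, cropping to
recording seconds [60, 180), amplitude clipping at +/-800 uV, resampling to
100 Hz, division by 30, and sliding-window extraction (length 1200, stride
519). All stages are pure functions of their inputs; everything runs in
float32.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "EEGRecording",
    "WindowSet",
    "PreprocessConfig",
    "DEFAULT_MONTAGE",
    "normalize_channel_name",
    "select_channels",
    "crop_recording",
    "clip_amplitude",
    "resample_to",
    "scale_amplitude",
    "extract_windows",
    "preprocess",
    "ChannelNotFoundError",
    "RecordingTooShortError",
]

#: Standard 21-electrode 10-20 set used across TUH-style clinical recordings.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "A1", "A2",
)

_CANONICAL = {name.upper(): name for name in DEFAULT_MONTAGE}


class ChannelNotFoundError(KeyError):
    """A montage channel could not be resolved in the recording."""


class RecordingTooShortError(ValueError):
    """Recording shorter than the 180 s the crop rule requires."""


def normalize_channel_name(raw: str) -> str:
    """Map vendor-style labels like ``"EEG FP1-REF"`` to canonical ``"Fp1"``.

    Unknown labels are returned stripped but otherwise untouched.
    """
    name = raw.strip()
    name = re.sub(r"^EEG\s+", "", name, flags=re.IGNORECASE)
    name = re.sub(r"-(REF|LE|AR)$", "", name, flags=re.IGNORECASE)
    name = name.strip()
    return _CANONICAL.get(name.upper(), name)


@dataclass
class EEGRecording:
    """Channel-major multichannel signal in microvolts with clinical context."""

    signal: np.ndarray                       # (C, S) float
    rate: float                              # Hz
    channel_names: tuple[str, ...]
    subject_meta: dict = field(default_factory=dict)  # age, gender, pathological
    report_text: str = ""
    recording_id: str = ""

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        self.channel_names = tuple(self.channel_names)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class WindowSet:
    """Fixed-shape stack of preprocessed windows with recording back-references."""

    windows: np.ndarray              # (n, C, T) float32
    recording_ids: np.ndarray        # (n,) object/str
    rate: float
    window_starts: np.ndarray = field(default=None)  # sample index of each window

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.recording_ids = np.asarray(self.recording_ids)
        if self.windows.ndim != 3:
            raise ValueError("windows must be an (n, C, T) tensor")
        if len(self.recording_ids) != len(self.windows):
            raise ValueError("one recording id per window required")
        if self.window_starts is None:
            self.window_starts = np.zeros(len(self.windows), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.windows)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        rate = sets[0].rate
        if any(s.rate != rate for s in sets):
            raise ValueError("window sets have differing rates")
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            recording_ids=np.concatenate([s.recording_ids for s in sets]),
            rate=rate,
            window_starts=np.concatenate([s.window_starts for s in sets]),
        )


@dataclass(frozen=True)
class PreprocessConfig:
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    crop_start_s: float = 60.0
    crop_duration_s: float = 120.0
    clip_uv: float = 800.0
    target_rate: float = 100.0
    divisor: float = 30.0
    window_length: int = 1200
    window_stride: int = 519


# ---------------------------------------------------------------------------
# stages


def select_channels(rec: EEGRecording, montage=DEFAULT_MONTAGE) -> EEGRecording:
    """Reorder/select the montage channels after alias normalization."""
    lookup = {}
    for i, raw in enumerate(rec.channel_names):
        lookup.setdefault(normalize_channel_name(raw).upper(), i)
    rows = []
    for name in montage:
        key = normalize_channel_name(name).upper()
        if key not in lookup:
            raise ChannelNotFoundError(
                f"montage channel {name!r} not found in recording channels "
                f"{list(rec.channel_names)}"
            )
        rows.append(lookup[key])
    return replace(
        rec,
        signal=np.ascontiguousarray(rec.signal[rows], dtype=np.float32),
        channel_names=tuple(normalize_channel_name(n) for n in montage),
    )


def crop_recording(rec: EEGRecording, start_s: float = 60.0,
                   duration_s: float = 120.0) -> EEGRecording:
    """Keep seconds [start, start + duration); reject shorter recordings."""
    needed = start_s + duration_s
    if rec.duration < needed:
        raise RecordingTooShortError(
            f"recording {rec.recording_id or '<unnamed>'} lasts "
            f"{rec.duration:.1f} s; {needed:.0f} s required"
        )
    lo = int(round(start_s * rec.rate))
    hi = lo + int(round(duration_s * rec.rate))
    return replace(rec, signal=np.ascontiguousarray(rec.signal[:, lo:hi]))


def clip_amplitude(rec: EEGRecording, bound: float = 800.0) -> EEGRecording:
    return replace(rec, signal=np.clip(rec.signal, -bound, bound))


def resample_to(rec: EEGRecording, target: float = 100.0) -> EEGRecording:
    """Polyphase resampling to ``target`` Hz; no-op when rates already match."""
    if target <= 0:
        raise ValueError("target rate must be positive")
    if rec.rate == target:
        return rec
    ratio = Fraction(target / rec.rate).limit_denominator(1000)
    signal = resample_poly(
        rec.signal.astype(np.float64), ratio.numerator, ratio.denominator, axis=1
    ).astype(np.float32)
    return replace(rec, signal=signal, rate=float(target))


def scale_amplitude(rec: EEGRecording, divisor: float = 30.0) -> EEGRecording:
    if divisor == 0:
        raise ValueError("divisor must be nonzero")
    return replace(rec, signal=(rec.signal / divisor).astype(np.float32))


def extract_windows(rec: EEGRecording, length: int = 1200,
                    stride: int = 519) -> WindowSet:
    """Complete sliding windows at starts 0, stride, 2*stride, ...

    A recording shorter than one window yields an empty set with a warning.
    """
    n_samples = rec.n_samples
    if n_samples < length:
        warnings.warn(
            f"recording {rec.recording_id or '<unnamed>'}: {n_samples} samples "
            f"< window length {length}; no windows emitted",
            stacklevel=2,
        )
        empty = np.empty((0, rec.signal.shape[0], length), dtype=np.float32)
        return WindowSet(empty, np.empty(0, dtype=object), rec.rate,
                         np.empty(0, dtype=np.int64))
    n_windows = (n_samples - length) // stride + 1
    starts = np.arange(n_windows, dtype=np.int64) * stride
    windows = np.stack(
        [rec.signal[:, s:s + length] for s in starts]
    ).astype(np.float32)
    ids = np.asarray([rec.recording_id] * n_windows, dtype=object)
    return WindowSet(windows, ids, rec.rate, starts)


def preprocess(rec: EEGRecording,
               config: PreprocessConfig = PreprocessConfig()) -> WindowSet:
    """Full chain: select -> crop -> clip -> resample -> scale -> window."""
    stages = [
        ("select_channels", lambda r: select_channels(r, config.montage)),
        ("crop_recording", lambda r: crop_recording(
            r, config.crop_start_s, config.crop_duration_s)),
        ("clip_amplitude", lambda r: clip_amplitude(r, config.clip_uv)),
        ("resample_to", lambda r: resample_to(r, config.target_rate)),
        ("scale_amplitude", lambda r: scale_amplitude(r, config.divisor)),
    ]
    out = rec
    for name, stage in stages:
        try:
            out = stage(out)
        except (ChannelNotFoundError, RecordingTooShortError, ValueError) as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
    # post-resampling amplitudes may slightly exceed the clip bound (ringing);
    # re-clip in scaled units so the documented bound holds exactly
    bound = config.clip_uv / config.divisor
    out = replace(out, signal=np.clip(out.signal, -bound, bound))
    ws = extract_windows(out, config.window_length, config.window_stride)
    if np.isnan(ws.windows).any():
        raise ValueError("NaN values after preprocessing")
    return ws


def expected_window_count(n_samples: int, length: int = 1200, stride: int = 519) -> int:
    """Closed-form window count, exposed for validation."""
    if n_samples < length:
        return 0
    return math.floor((n_samples - length) / stride) + 1
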