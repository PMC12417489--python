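"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF profile this package needs: identical sampling rate
per channel on write, per-channel rates on read (callers resample to a common
rate before preprocessing), 16-bit samples with linear physical scaling.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .preprocessing import EEGRecording

__all__ = ["write_edf", "write_edf_multirate", "read_edf"]

_HDR = 256


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording, physical_max: float = 8000.0) -> None:
    """Write a channel-major microvolt signal as a plain EDF file.

    Uses 1-second data records; a trailing partial second is dropped.
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    rate = int(round(rate))
    n_channels, n_samples = rec.signal.shape
    n_records = n_samples // rate
    if n_records == 0:
        raise ValueError("recording shorter than one 1-second data record")

    pmin, pmax = -physical_max, physical_max
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                        # local patient id
        _field("Startdate 01-JAN-2000", 80),          # local recording id
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(str(_HDR * (1 + n_channels)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),                               # record duration (s)
        _field(str(n_channels), 4),
    ])
    labels = b"".join(_field(name, 16) for name in rec.channel_names)
    transducer = b"".join(_field("", 80) for _ in range(n_channels))
    dimension = b"".join(_field("uV", 8) for _ in range(n_channels))
    phys_min = b"".join(_field(f"{pmin:g}", 8) for _ in range(n_channels))
    phys_max = b"".join(_field(f"{pmax:g}", 8) for _ in range(n_channels))
    dig_min = b"".join(_field(str(dmin), 8) for _ in range(n_channels))
    dig_max = b"".join(_field(str(dmax), 8) for _ in range(n_channels))
    prefilter = b"".join(_field("", 80) for _ in range(n_channels))
    samples_per_rec = b"".join(_field(str(rate), 8) for _ in range(n_channels))
    reserved = b"".join(_field("", 32) for _ in range(n_channels))

    clipped = np.clip(rec.signal[:, : n_records * rate], pmin, pmax)
    digital = np.round((clipped - pmin) * gain + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dimension + phys_min + phys_max
                 + dig_min + dig_max + prefilter + samples_per_rec + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * rate:(r + 1) * rate].tobytes())


def write_edf_multirate(path, signals: list[np.ndarray], rates: list[float],
                        channel_names: list[str],
                        physical_max: float = 8000.0) -> None:
    """Write channels with differing integer sampling rates (1-s records)."""
    rates = [int(round(r)) for r in rates]
    if not (len(signals) == len(rates) == len(channel_names)):
        raise ValueError("signals, rates and channel names must align")
    n_records = min(len(s) // r for s, r in zip(signals, rates))
    if n_records == 0:
        raise ValueError("recording shorter than one 1-second data record")
    pmin, pmax = -physical_max, physical_max
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    n_channels = len(signals)

    header = b"".join([
        _field("0", 8), _field("X X X X", 80),
        _field("Startdate 01-JAN-2000", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(str(_HDR * (1 + n_channels)), 8), _field("", 44),
        _field(str(n_records), 8), _field("1", 8), _field(str(n_channels), 4),
    ])
    parts = [header,
             b"".join(_field(n, 16) for n in channel_names),
             b"".join(_field("", 80) for _ in range(n_channels)),
             b"".join(_field("uV", 8) for _ in range(n_channels)),
             b"".join(_field(f"{pmin:g}", 8) for _ in range(n_channels)),
             b"".join(_field(f"{pmax:g}", 8) for _ in range(n_channels)),
             b"".join(_field(str(dmin), 8) for _ in range(n_channels)),
             b"".join(_field(str(dmax), 8) for _ in range(n_channels)),
             b"".join(_field("", 80) for _ in range(n_channels)),
             b"".join(_field(str(r), 8) for r in rates),
             b"".join(_field("", 32) for _ in range(n_channels))]
    digitals = [np.round((np.clip(s[: n_records * r], pmin, pmax) - pmin)
                         * gain + dmin).astype("<i2")
                for s, r in zip(signals, rates)]
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for rec in range(n_records):
            for d, r in zip(digitals, rates):
                fh.write(d[rec * r:(rec + 1) * r].tobytes())


def read_edf(path) -> EEGRecording:
    """Read a plain EDF file into microvolts (float32)."""
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        n_channels = int(head[252:256])

        def chan_fields(width):
            raw = fh.read(width * n_channels)
            return [raw[i * width:(i + 1) * width].decode("ascii").strip()
                    for i in range(n_channels)]

        labels = chan_fields(16)
        chan_fields(80)   # transducer
        chan_fields(8)    # dimension
        pmins = [float(v) for v in chan_fields(8)]
        pmaxs = [float(v) for v in chan_fields(8)]
        dmins = [float(v) for v in chan_fields(8)]
        dmaxs = [float(v) for v in chan_fields(8)]
        chan_fields(80)   # prefilter
        counts = [int(v) for v in chan_fields(8)]
        chan_fields(32)   # reserved

        per_record = sum(counts)
        raw = np.frombuffer(fh.read(per_record * n_records * 2), dtype="<i2")

    raw = raw.reshape(n_records, per_record)
    offsets = np.cumsum([0] + counts)
    channels = []
    for c in range(n_channels):
        digital = raw[:, offsets[c]:offsets[c + 1]].reshape(-1).astype(np.float64)
        gain = (pmaxs[c] - pmins[c]) / (dmaxs[c] - dmins[c])
        channels.append(((digital - dmins[c]) * gain + pmins[c]
                         ).astype(np.float32))

    # per-channel rates are allowed: resample everything to the highest rate
    # before assembling the channel-major matrix
    common = max(counts)
    if len(set(counts)) != 1:
        from fractions import Fraction
        from scipy.signal import resample_poly
        for c in range(n_channels):
            if counts[c] != common:
                ratio = Fraction(common, counts[c])
                channels[c] = resample_poly(
                    channels[c].astype(np.float64), ratio.numerator,
                    ratio.denominator).astype(np.float32)
    rate = common / record_dur
    if abs(rate - round(rate)) < 1e-9:
        rate = round(rate)
    signal = np.stack(channels)
    return EEGRecording(signal=signal, rate=float(rate),
                        channel_names=tuple(labels))
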