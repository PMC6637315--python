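"""Minimal EDF (European Data Format) reader/writer.

Supports only what the package needs: continuous recordings with an
integer sampling rate, 1-second data records, 16-bit samples.  The writer
exists mainly so the reader can be exercised; the public API exposes EDF
read-only.  Physical scaling follows the EDF spec: the digital range
[dig_min, dig_max] maps linearly onto [phys_min, phys_max], so the
round-trip quantization step is (phys_max - phys_min) / (dig_max - dig_min).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

DIG_MIN, DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width} bytes")
    return b.ljust(width)


def quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (DIG_MAX - DIG_MIN)


def write_edf(path: str | Path, recording) -> None:
    """Write an EDF file with 1-second records (fs must be an integer).

    Trailing samples that do not fill a whole record are dropped.
    """
    fs = recording.fs
    if fs != int(fs):
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    spr = int(fs)
    names = list(recording.channels)
    ns = len(names)
    n_records = recording.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")

    digital = []
    phys_ranges = []
    for name in names:
        sig = recording.channels[name][: n_records * spr]
        lo, hi = float(sig.min()), float(sig.max())
        if hi == lo:  # avoid a zero physical range
            hi = lo + 1.0
        scale = (DIG_MAX - DIG_MIN) / (hi - lo)
        dig = np.round((sig - lo) * scale + DIG_MIN).astype("<i2")
        digital.append(dig.reshape(n_records, spr))
        phys_ranges.append((lo, hi))

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X", 80),
            _pad("X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_pad(n, 16) for n in names),
            b"".join(_pad("", 80) for _ in names),
            b"".join(_pad("", 8) for _ in names),
            b"".join(_pad(f"{lo:.7g}"[:8], 8) for lo, _ in phys_ranges),
            b"".join(_pad(f"{hi:.7g}"[:8], 8) for _, hi in phys_ranges),
            b"".join(_pad(str(DIG_MIN), 8) for _ in names),
            b"".join(_pad(str(DIG_MAX), 8) for _ in names),
            b"".join(_pad("", 80) for _ in names),
            b"".join(_pad(str(spr), 8) for _ in names),
            b"".join(_pad("", 32) for _ in names),
        ]
    )
    with Path(path).open("wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            for c in range(ns):
                fh.write(digital[c][r].tobytes())


def read_edf(path: str | Path):
    """Read an EDF file into a :class:`~emgdi.io.Recording`.

    All signals must share one sampling rate (equal samples-per-record and
    record duration); physical units are taken from the per-signal scaling
    fields.
    """
    from .io import Recording, RecordingParseError

    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise RecordingParseError(f"{path}: truncated EDF header")

    def field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", "replace").strip()

    n_records = int(field(236, 8))
    record_dur = float(field(244, 8))
    ns = int(field(252, 4))
    off = 256

    def sig_fields(width: int) -> list[str]:
        nonlocal off
        vals = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(ns)
        ]
        off += ns * width
        return vals

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # dimension
    phys_min = [float(v) for v in sig_fields(8)]
    phys_max = [float(v) for v in sig_fields(8)]
    dig_min = [int(v) for v in sig_fields(8)]
    dig_max = [int(v) for v in sig_fields(8)]
    sig_fields(80)  # prefilter
    spr = [int(v) for v in sig_fields(8)]
    sig_fields(32)  # reserved

    if len(set(spr)) != 1:
        raise RecordingParseError(f"{path}: mixed per-signal sampling rates")
    fs = spr[0] / record_dur
    header_bytes = 256 * (1 + ns)
    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    expected = n_records * sum(spr)
    if len(data) < expected:
        raise RecordingParseError(f"{path}: truncated EDF data section")
    data = data[:expected].reshape(n_records, ns, spr[0])

    channels = {}
    for i, label in enumerate(labels):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels[label] = (
            (data[:, i, :].reshape(-1).astype(float) - dig_min[i]) * gain + phys_min[i]
        )
    return Recording(fs=fs, channels=channels)
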