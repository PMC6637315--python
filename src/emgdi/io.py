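"""Recording container and delimited-text / EDF input-output.

The native on-disk format is a tab-separated text file::

    # fs=1000
    # t0=0
    # marker\t30.5\tic_maneuver
    emg_1\temg_2\temg_3\temg_4\temg_5\tecg\tflow
    0.001\t...

Floats are written with ``%.17g`` so a write/read round trip is bit exact.
Sample ``i`` covers the half-open time interval ``[i/fs, (i+1)/fs)``; all
interval bookkeeping downstream uses half-open sample index ranges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "EventMarker",
    "Recording",
    "RecordingError",
    "RecordingParseError",
    "read_recording",
    "write_recording",
    "resample",
]

#: closed marker vocabulary; ``minute_<k>`` is also accepted.
MARKER_LABELS = {
    "rest_start",
    "unloaded_start",
    "loaded_start",
    "ic_maneuver",
    "test_end",
}
_MINUTE_RE = re.compile(r"^minute_\d+$")

#: channel roles the analysis pipeline requires.
REQUIRED_ROLES = ("ecg", "flow")


class RecordingError(ValueError):
    """Invalid recording structure (missing channel, bad fs, ...)."""


class RecordingParseError(RecordingError):
    """Malformed recording file."""


def _valid_label(label: str) -> bool:
    return label in MARKER_LABELS or bool(_MINUTE_RE.match(label))


@dataclass(frozen=True)
class EventMarker:
    """A timestamped event; times are seconds on the recording time axis."""

    time_s: float
    label: str

    def __post_init__(self) -> None:
        if not _valid_label(self.label):
            raise RecordingError(
                f"unknown marker label {self.label!r}; expected one of "
                f"{sorted(MARKER_LABELS)} or minute_<k>"
            )


@dataclass
class Recording:
    """Aligned multi-channel signals at a single sampling rate.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    channels : dict[str, np.ndarray]
        Ordered mapping of channel name to samples.  Names ``emg_1`` ...
        ``emg_5`` are EMG channels (volts), ``ecg`` the reference ECG
        (volts) and ``flow`` respiratory flow in L/s with *negative*
        values during inspiration.
    markers : list[EventMarker]
        Optional event markers (seconds from ``t0``-relative record start).
    t0 : float
        Time of sample 0 in seconds.
    """

    fs: float
    channels: dict[str, np.ndarray]
    markers: list[EventMarker] = field(default_factory=list)
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise RecordingError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise RecordingError("recording has no channels")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise RecordingError(f"channel lengths differ: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }
        times = [m.time_s for m in self.markers]
        if any(b < a for a, b in zip(times, times[1:])):
            raise RecordingError("marker times must be non-decreasing")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def emg_names(self) -> list[str]:
        return [n for n in self.channels if n.startswith("emg")]

    def require(self, *roles: str) -> None:
        for role in roles:
            if role not in self.channels:
                raise RecordingError(f"{role} channel required")

    def marker_times(self, label: str) -> list[float]:
        return [m.time_s for m in self.markers if m.label == label]

    def copy(self) -> "Recording":
        return Recording(
            fs=self.fs,
            channels={n: s.copy() for n, s in self.channels.items()},
            markers=list(self.markers),
            t0=self.t0,
            meta=dict(self.meta),
        )


def write_recording(path: str | Path, recording: Recording) -> None:
    """Write a recording in the native delimited-text format (bit exact)."""
    path = Path(path)
    lines = [f"# fs={recording.fs!r}", f"# t0={recording.t0!r}"]
    for m in recording.markers:
        lines.append(f"# marker\t{m.time_s!r}\t{m.label}")
    lines.append("\t".join(recording.channels))
    data = np.column_stack(list(recording.channels.values()))
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, fmt="%.17g", delimiter="\t")


def read_recording(path: str | Path, format: str = "delimited_text") -> Recording:
    """Read a recording from ``delimited_text`` (native) or ``edf``.

    Raises
    ------
    RecordingError
        If a required channel role (``ecg``, ``flow``) is absent.
    RecordingParseError
        On malformed headers or ragged numeric rows (the offending line
        number is included in the message).
    """
    path = Path(path)
    if format == "edf":
        from . import _edf

        rec = _edf.read_edf(path)
    elif format == "delimited_text":
        rec = _read_text(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    rec.require(*REQUIRED_ROLES)
    return rec


def _read_text(path: Path) -> Recording:
    fs = None
    t0 = 0.0
    markers: list[EventMarker] = []
    names: list[str] | None = None
    header_end = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("t0="):
                    t0 = float(body[3:])
                elif body.startswith("marker"):
                    parts = body.split("\t")
                    if len(parts) != 3:
                        raise RecordingParseError(
                            f"{path}:{lineno}: malformed marker line {line!r}"
                        )
                    markers.append(EventMarker(float(parts[1]), parts[2]))
                continue
            names = line.split("\t")
            header_end = lineno
            break
    if fs is None:
        raise RecordingParseError(f"{path}: missing '# fs=<Hz>' header")
    if not names or names == [""]:
        raise RecordingParseError(f"{path}: missing channel-name header line")
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=header_end, ndmin=2)
    except ValueError as exc:
        raise RecordingParseError(f"{path}: {exc}") from exc
    if data.shape[1] != len(names):
        raise RecordingParseError(
            f"{path}: header declares {len(names)} channels but rows have "
            f"{data.shape[1]} columns"
        )
    channels = {name: data[:, i] for i, name in enumerate(names)}
    return Recording(fs=fs, channels=channels, markers=markers, t0=t0)


def resample(recording: Recording, target_fs: float) -> Recording:
    """Anti-alias filtered (polyphase) resampling to a lower rate.

    Marker times are stored in seconds and survive unchanged.  Upsampling
    is rejected: the analysis chain only ever decimates (e.g. a 2000 Hz
    acquisition exported at 1000 Hz).
    """
    if target_fs > recording.fs:
        raise RecordingError(
            f"upsampling not supported ({recording.fs} -> {target_fs} Hz)"
        )
    if target_fs == recording.fs:
        return recording.copy()
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    channels = {
        name: resample_poly(sig, up, down) for name, sig in recording.channels.items()
    }
    return Recording(
        fs=target_fs,
        channels=channels,
        markers=list(recording.markers),
        t0=recording.t0,
        meta=dict(recording.meta),
    )
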