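"""High-pass filtering and moving-window RMS envelopes.

Both analysis paths (reference-channel adaptive cleaning and the manual
between-QRS emulation) run the same chain: 20 Hz zero-phase high-pass to
strip motion artifact, then a moving root-mean-square envelope.  The
high-pass is a 4th-order Butterworth applied forward-backward so envelope
timing stays aligned with the flow signal.  The RMS window is truncated at
the record edges rather than padded, so no fabricated samples enter
breath-windowed means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

DEFAULT_HIGHPASS_HZ = 20.0
DEFAULT_RMS_WINDOW_S = 0.05


@dataclass
class EnvelopeSignal:
    """Moving-RMS amplitude of one channel; ``values`` is in volts."""

    values: np.ndarray
    fs: float
    window_s: float
    source_channel: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def highpass(
    signal: np.ndarray, fs: float, cutoff: float = DEFAULT_HIGHPASS_HZ, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth high-pass (DC removed, passband gain ~1)."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2)=(0, {fs / 2}), got {cutoff}")
    sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def rms_envelope(
    signal: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_RMS_WINDOW_S,
    source_channel: str = "",
) -> EnvelopeSignal:
    """Centered moving-window RMS with edge truncation.

    The window length is ``round(window_s * fs)`` samples (at least 1); at
    the record edges the window shrinks to the available samples.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    x = np.asarray(signal, dtype=float)
    n = len(x)
    n_w = int(round(window_s * fs))
    if n_w < 1:
        raise ValueError(
            f"window_s * fs = {window_s * fs:.3g} < 1; window shorter than one sample"
        )
    left = n_w // 2
    idx = np.arange(n)
    starts = np.clip(idx - left, 0, n)
    ends = np.clip(idx - left + n_w, 0, n)
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    mean_sq = (csum[ends] - csum[starts]) / np.maximum(ends - starts, 1)
    values = np.sqrt(np.maximum(mean_sq, 0.0))
    return EnvelopeSignal(values=values, fs=fs, window_s=window_s, source_channel=source_channel)
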