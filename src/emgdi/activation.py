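"""Per-breath amplitude statistics and per-minute activation summaries.

The automated path computes, for every marked inspiration, the mean (and
peak) of the RMS envelope; normalizes by the largest RMS amplitude
observed during any inspiratory-capacity maneuver (the maximal-activation
reference); and averages all usable tidal breaths of each minute into one
relative-activation percentage.  Reporting uses the single channel whose
IC-maneuver amplitudes are largest on average; a per-breath best-of-five
variant is available via ``channel_mode='per_breath_max'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breaths import BreathInterval
from .cancel import LmsConfig, clean_recording
from .preprocess import DEFAULT_HIGHPASS_HZ, DEFAULT_RMS_WINDOW_S, highpass, rms_envelope

__all__ = [
    "BreathActivation",
    "breath_mean_rms",
    "compute_emgdimax",
    "select_reporting_channel",
    "minute_summary",
    "analyze_recording",
]

METHODS = ("semi_auto", "manual_highest", "manual_widest")


@dataclass(frozen=True)
class BreathActivation:
    breath_id: int
    channel: str
    mean_rms: float  # volts
    peak_rms: float  # volts
    method: str = "semi_auto"

    def __post_init__(self) -> None:
        if not 0 <= self.mean_rms <= self.peak_rms:
            raise ValueError(
                f"breath {self.breath_id}: need 0 <= mean_rms <= peak_rms, "
                f"got {self.mean_rms}, {self.peak_rms}"
            )


def breath_mean_rms(
    envelope, breath: BreathInterval, channel: str = "", method: str = "semi_auto"
) -> BreathActivation:
    """Mean and peak of the RMS envelope over one inspiration."""
    env = np.asarray(envelope, dtype=float)
    seg = env[breath.insp_start : breath.insp_end]
    if len(seg) == 0:
        raise ValueError(f"breath {breath.breath_id}: empty inspiratory interval")
    peak = float(seg.max())
    # the accumulated mean of a constant segment can exceed its max by 1 ulp
    mean = min(float(seg.mean()), peak)
    return BreathActivation(
        breath_id=breath.breath_id,
        channel=channel,
        mean_rms=mean,
        peak_rms=peak,
        method=method,
    )


def compute_emgdimax(
    ic_breaths: list[BreathInterval],
    envelopes_by_channel: dict[str, np.ndarray],
    stat: str = "peak",
) -> tuple[float, dict]:
    """Maximal-activation reference over all IC inspirations and channels.

    ``stat='peak'`` takes the largest envelope sample (the default,
    "largest RMS amplitude"); ``stat='mean'`` takes the largest per-breath
    envelope mean instead.
    """
    if not ic_breaths:
        raise ValueError(
            "no IC maneuvers found - supply ic_maneuver markers or enable "
            "volume-based IC detection"
        )
    if stat not in ("peak", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    best_val, source = -np.inf, {}
    for name, env in envelopes_by_channel.items():
        env = np.asarray(env, dtype=float)
        for b in ic_breaths:
            seg = env[b.insp_start : b.insp_end]
            if len(seg) == 0:
                continue
            val = float(seg.max() if stat == "peak" else seg.mean())
            if val > best_val:
                best_val = val
                source = {"breath_id": b.breath_id, "channel": name, "stat": stat}
    return best_val, source


def select_reporting_channel(
    ic_breaths: list[BreathInterval], envelopes_by_channel: dict[str, np.ndarray]
) -> str:
    """Channel with the largest average per-IC peak envelope (ties -> lowest index)."""
    if not ic_breaths:
        raise ValueError("no IC maneuvers available for channel selection")
    scores = {}
    for name, env in envelopes_by_channel.items():
        env = np.asarray(env, dtype=float)
        peaks = [env[b.insp_start : b.insp_end].max() for b in ic_breaths]
        scores[name] = float(np.mean(peaks))
    best = max(scores, key=lambda name: (scores[name], -_channel_rank(name)))
    return best


def _channel_rank(name: str) -> int:
    try:
        return int(name.rsplit("_", 1)[-1])
    except ValueError:
        return 0


def minute_summary(
    activations: list[BreathActivation],
    breaths: list[BreathInterval],
    emgdimax: float,
    reporting_channel: str = "",
) -> pd.DataFrame:
    """Per-minute mean EMG/max% over usable tidal breaths.

    IC maneuvers and flagged breaths are excluded; minutes with no usable
    breath are simply absent from the table (missing, never zero).
    """
    if emgdimax <= 0:
        raise ValueError(f"emgdimax must be positive, got {emgdimax}")
    by_id = {b.breath_id: b for b in breaths}
    rows: dict[int, list] = {}
    phases: dict[int, str] = {}
    for act in activations:
        b = by_id.get(act.breath_id)
        if b is None or b.is_ic or not b.usable:
            continue
        if b.minute_index is None or b.minute_index < 1:
            continue
        rows.setdefault(b.minute_index, []).append(act.mean_rms)
        phases[b.minute_index] = b.phase
    records = [
        {
            "minute_index": m,
            "phase": phases[m],
            "emgdi_pct": 100.0 * float(np.mean(vals)) / emgdimax,
            "n_breaths_used": len(vals),
            "emgdimax_v": emgdimax,
            "reporting_channel": reporting_channel,
        }
        for m, vals in sorted(rows.items())
    ]
    return pd.DataFrame(
        records,
        columns=[
            "minute_index",
            "phase",
            "emgdi_pct",
            "n_breaths_used",
            "emgdimax_v",
            "reporting_channel",
        ],
    )


def analyze_recording(
    recording,
    breaths: list[BreathInterval],
    clean: bool = True,
    lms_config: LmsConfig | None = None,
    highpass_hz: float | None = DEFAULT_HIGHPASS_HZ,
    rms_window_s: float = DEFAULT_RMS_WINDOW_S,
    channel_mode: str = "fixed",
    emgdimax_stat: str = "peak",
) -> tuple[pd.DataFrame, dict]:
    """Full automated path: (high-pass -> adaptive cleaning ->) RMS ->
    per-breath means -> per-minute summary.

    ``channel_mode='fixed'`` (default) reports the pre-selected best
    channel; ``'per_breath_max'`` takes the highest channel per breath.
    Returns ``(per_minute_table, info)``.
    """
    rec = recording.copy()
    if highpass_hz is not None:
        for name in rec.emg_names + ["ecg"]:
            rec.channels[name] = highpass(rec.channels[name], rec.fs, highpass_hz)
    if clean:
        rec, _ = clean_recording(rec, lms_config)
    envelopes = {
        name: rms_envelope(rec.channels[name], rec.fs, rms_window_s, name).values
        for name in rec.emg_names
    }
    ic_breaths = [b for b in breaths if b.is_ic]
    emgdimax, source = compute_emgdimax(ic_breaths, envelopes, stat=emgdimax_stat)
    channel = select_reporting_channel(ic_breaths, envelopes)

    activations = []
    for b in breaths:
        if b.is_ic or not b.usable:
            continue
        if channel_mode == "fixed":
            activations.append(breath_mean_rms(envelopes[channel], b, channel))
        elif channel_mode == "per_breath_max":
            acts = [breath_mean_rms(envelopes[n], b, n) for n in envelopes]
            activations.append(max(acts, key=lambda a: a.mean_rms))
        else:
            raise ValueError(f"unknown channel_mode {channel_mode!r}")
    table = minute_summary(activations, breaths, emgdimax, reporting_channel=channel)
    info = {
        "emgdimax_v": emgdimax,
        "emgdimax_source": source,
        "reporting_channel": channel,
        "n_ic": len(ic_breaths),
        "cleaned": clean,
    }
    return table, info
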