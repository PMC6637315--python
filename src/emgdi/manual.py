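"""Emulation of the manual between-QRS amplitude analysis.

The manual workflow blanks a window around every detected R peak and lets
a rater pick one contamination-free interval per inspiration.  Two
documented selection strategies are modelled: ``highest`` (the interval
with the largest envelope mean; ties go to the *latest* interval,
matching the end-inspiratory tendency) and ``widest`` (the longest
interval; ties go to the *earliest*).  Minute values average the selected
interval means of the last few usable breaths of the minute, normalized
by a maximal-activation reference obtained with the same machinery on IC
maneuvers.  P/T-wave energy outside the blanked window deliberately leaks
into the estimates: no instructions on residual interference are part of
the emulated protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breaths import BreathInterval
from .preprocess import DEFAULT_HIGHPASS_HZ, DEFAULT_RMS_WINDOW_S, highpass, rms_envelope

__all__ = [
    "QrsAnnotation",
    "CleanInterval",
    "detect_qrs",
    "enumerate_clean_intervals",
    "select_interval",
    "manual_minute_estimate",
    "manual_emgdimax",
    "emulate_manual",
]

STRATEGIES = ("highest", "widest")


@dataclass
class QrsAnnotation:
    """R-peak indices plus merged half-open blanked sample intervals."""

    r_peaks: np.ndarray
    blank_pre_s: float
    blank_post_s: float
    blanked: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class CleanInterval:
    """A contamination-free sub-interval of one inspiration."""

    start: int
    end: int
    width_s: float
    mean_rms: float


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def detect_qrs(
    ecg: np.ndarray,
    fs: float,
    threshold_frac: float = 0.5,
    refractory_s: float = 0.2,
    blank_pre_s: float = 0.06,
    blank_post_s: float = 0.10,
    baseline_window_s: float = 2.0,
) -> QrsAnnotation:
    """Amplitude-threshold R-peak detection on the reference ECG.

    The threshold is ``threshold_frac`` times a blockwise near-maximum of
    |ecg| (linearly interpolated between block centers), which adapts to
    slow amplitude drift while sitting safely above P/T deflections.  A
    refractory separation keeps the largest peak in each conflict.  Zero
    input yields an empty annotation.
    """
    from scipy.signal import find_peaks

    ecg = np.asarray(ecg, dtype=float)
    n = len(ecg)
    mag = np.abs(ecg)
    if n == 0 or mag.max() == 0:
        return QrsAnnotation(np.array([], dtype=int), blank_pre_s, blank_post_s, [])

    block = max(1, int(round(baseline_window_s * fs)))
    n_blocks = max(1, n // block)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    centers = (edges[:-1] + edges[1:]) / 2.0
    block_max = np.array([mag[a:b].max() for a, b in zip(edges[:-1], edges[1:])])
    baseline = np.interp(np.arange(n), centers, block_max)
    height = threshold_frac * baseline

    peaks, _ = find_peaks(mag, distance=max(1, int(round(refractory_s * fs))))
    peaks = peaks[mag[peaks] >= height[peaks]]

    pre = int(round(blank_pre_s * fs))
    post = int(round(blank_post_s * fs))
    blanked = _merge_intervals(
        [(max(0, int(r) - pre), min(n, int(r) + post)) for r in peaks]
    )
    return QrsAnnotation(peaks.astype(int), blank_pre_s, blank_post_s, blanked)


def enumerate_clean_intervals(
    breath: BreathInterval,
    qrs: QrsAnnotation,
    envelope,
    fs: float,
    min_interval_s: float = 0.05,
) -> list[CleanInterval]:
    """Maximal sub-intervals of the inspiration disjoint from blanking.

    May be empty (the breath is then unusable for the manual method, e.g.
    when QRS complexes bury the whole inspiration).
    """
    env = np.asarray(envelope, dtype=float)
    free: list[tuple[int, int]] = []
    cursor = breath.insp_start
    for a, b in qrs.blanked:
        if b <= breath.insp_start or a >= breath.insp_end:
            continue
        if a > cursor:
            free.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < breath.insp_end:
        free.append((cursor, breath.insp_end))
    out = []
    for a, b in free:
        width = (b - a) / fs
        if width >= min_interval_s:
            out.append(CleanInterval(a, b, width, float(env[a:b].mean())))
    return out


def select_interval(intervals: list[CleanInterval], strategy: str) -> CleanInterval:
    """Pick one interval per the rater strategy (documented tie-breaks)."""
    if not intervals:
        raise ValueError("no contamination-free interval available for this breath")
    if strategy == "highest":
        return max(intervals, key=lambda iv: (iv.mean_rms, iv.start))
    if strategy == "widest":
        return max(intervals, key=lambda iv: (iv.width_s, -iv.start))
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def _selected_means(
    breaths: list[BreathInterval],
    envelope,
    qrs: QrsAnnotation,
    fs: float,
    strategy: str,
    min_interval_s: float,
) -> tuple[list[float], list[CleanInterval], list[BreathInterval]]:
    means, chosen, used = [], [], []
    for b in breaths:
        ivs = enumerate_clean_intervals(b, qrs, envelope, fs, min_interval_s)
        if not ivs:
            continue
        iv = select_interval(ivs, strategy)
        means.append(iv.mean_rms)
        chosen.append(iv)
        used.append(b)
    return means, chosen, used


def manual_minute_estimate(
    breaths: list[BreathInterval],
    envelope,
    qrs: QrsAnnotation,
    fs: float,
    strategy: str,
    n_rep: int = 5,
    min_interval_s: float = 0.05,
) -> tuple[float, int, list[CleanInterval]]:
    """Average selected-interval mean over the last ``n_rep`` usable tidal
    breaths of one minute (all of them if fewer are available).

    Returns ``(mean_volts, n_used, selected_intervals)``; breaths with no
    selectable interval are skipped.
    """
    tidal = [b for b in breaths if not b.is_ic and b.usable]
    if not tidal:
        raise ValueError("no usable tidal breath in this minute")
    means, chosen, used = _selected_means(
        tidal, envelope, qrs, fs, strategy, min_interval_s
    )
    if not means:
        raise ValueError("no breath of this minute has a contamination-free interval")
    means, chosen = means[-n_rep:], chosen[-n_rep:]
    return float(np.mean(means)), len(means), chosen


def manual_emgdimax(
    ic_breaths: list[BreathInterval],
    envelope,
    qrs: QrsAnnotation,
    fs: float,
    min_interval_s: float = 0.05,
) -> float:
    """Maximal-activation reference read off IC maneuvers between QRS complexes.

    The reference is the largest RMS amplitude (envelope peak), so the
    blanking only restricts *where* it may be read: the peak is taken over
    the contamination-free intervals of every IC inspiration.  Activity
    buried under a QRS complex is unavailable, exactly as for tidal breaths.
    """
    env = np.asarray(envelope, dtype=float)
    best = -np.inf
    for b in ic_breaths:
        for iv in enumerate_clean_intervals(b, qrs, env, fs, min_interval_s):
            best = max(best, float(env[iv.start : iv.end].max()))
    if not np.isfinite(best):
        raise ValueError("no IC maneuver offers a contamination-free interval")
    return best


def emulate_manual(
    recording,
    breaths: list[BreathInterval],
    strategy: str,
    n_rep: int = 5,
    min_interval_s: float = 0.05,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    rms_window_s: float = DEFAULT_RMS_WINDOW_S,
    qrs_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full manual-method emulation on a (contaminated) recording.

    The reporting channel is chosen, as a rater would, from the largest
    between-QRS amplitudes during IC maneuvers - never from blanked
    samples, where the contaminated envelope is dominated by the R spikes.
    Returns ``(per_minute_table, audit_table, info)``; the audit table
    records the selected cursor positions per breath for traceability.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    recording.require("ecg")
    fs = recording.fs
    qrs = detect_qrs(recording.channels["ecg"], fs, **(qrs_kwargs or {}))
    envelopes = {
        name: rms_envelope(highpass(recording.channels[name], fs, highpass_hz), fs, rms_window_s).values
        for name in recording.emg_names
    }
    ic_breaths = [b for b in breaths if b.is_ic]
    if not ic_breaths:
        raise ValueError("no IC maneuvers flagged; run IC detection first")
    scores = {}
    for name, e in envelopes.items():
        try:
            scores[name] = manual_emgdimax(ic_breaths, e, qrs, fs, min_interval_s)
        except ValueError:
            continue
    if not scores:
        raise ValueError("no IC maneuver offers a contamination-free interval")
    channel = min(scores, key=lambda name: (-scores[name], name))
    env = envelopes[channel]
    emgdimax = scores[channel]

    by_minute: dict[int, list[BreathInterval]] = {}
    for b in breaths:
        if b.minute_index is not None and b.minute_index >= 1:
            by_minute.setdefault(b.minute_index, []).append(b)

    rows, audit = [], []
    for minute, group in sorted(by_minute.items()):
        try:
            value, n_used, chosen = manual_minute_estimate(
                group, env, qrs, fs, strategy, n_rep, min_interval_s
            )
        except ValueError:
            continue
        rows.append(
            {
                "minute_index": minute,
                "phase": group[0].phase,
                "emgdi_pct": 100.0 * value / emgdimax,
                "n_breaths_used": n_used,
                "emgdimax_v": emgdimax,
                "reporting_channel": channel,
            }
        )
        for iv in chosen:
            audit.append(
                {
                    "minute_index": minute,
                    "start_s": iv.start / fs,
                    "end_s": iv.end / fs,
                    "mean_rms_v": iv.mean_rms,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "minute_index",
            "phase",
            "emgdi_pct",
            "n_breaths_used",
            "emgdimax_v",
            "reporting_channel",
        ],
    )
    info = {
        "strategy": strategy,
        "emgdimax_v": emgdimax,
        "reporting_channel": channel,
        "n_r_peaks": int(len(qrs.r_peaks)),
    }
    return table, pd.DataFrame(audit), info
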