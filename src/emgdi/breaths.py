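"""Breath segmentation from the flow signal and breath bookkeeping.

Inspiration is negative flow.  A breath is the half-open sample span
[insp_start, exp_end) where insp_start and insp_end sit on zero crossings
of flow.  Candidate crossings are validated with hysteresis: an excursion
only counts if |flow| stays beyond a small threshold for a minimum hold
time, which suppresses chatter from noise-level crossings; the reported
boundary is then walked back to the true zero crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreathInterval",
    "detect_breaths",
    "detect_ic_maneuvers",
    "assign_minutes",
    "exclude_outlier_breaths",
    "breaths_to_frame",
]

QUALITY_OK = "ok"
QUALITY_SHORT = "excluded_short"
QUALITY_NOISY = "excluded_noisy"


@dataclass
class BreathInterval:
    """One breath: inspiration [insp_start, insp_end), expiration [insp_end, exp_end)."""

    breath_id: int
    insp_start: int
    insp_end: int
    exp_end: int
    is_ic: bool = False
    minute_index: int | None = None
    phase: str = "test"
    quality: str = QUALITY_OK

    def __post_init__(self) -> None:
        if not self.insp_start < self.insp_end <= self.exp_end:
            raise ValueError(
                f"breath {self.breath_id}: require insp_start < insp_end <= exp_end, "
                f"got {self.insp_start}, {self.insp_end}, {self.exp_end}"
            )

    @property
    def usable(self) -> bool:
        return self.quality == QUALITY_OK

    def ti_s(self, fs: float) -> float:
        return (self.insp_end - self.insp_start) / fs


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_breaths(
    flow: np.ndarray,
    fs: float,
    min_insp_s: float = 0.3,
    min_amplitude: float = 0.1,
    hysteresis_lps: float = 0.05,
    hysteresis_hold_s: float = 0.05,
) -> list[BreathInterval]:
    """Segment breaths at zero-flow points with hysteresis validation.

    An inspiratory onset is the negative-going zero crossing preceding a
    validated negative excursion (|flow| > ``hysteresis_lps`` sustained for
    ``hysteresis_hold_s``); the inspiratory end is the following
    positive-going crossing; the expiratory end is the next onset (or the
    next negative-going crossing for the final breath).  Candidates whose
    inspiration is shorter than ``min_insp_s`` or whose peak inspiratory
    flow is below ``min_amplitude`` are dropped.
    """
    flow = np.asarray(flow, dtype=float)
    n = len(flow)
    hold = max(1, int(round(hysteresis_hold_s * fs)))

    neg_cores = [(a, b) for a, b in _runs(flow < -hysteresis_lps) if b - a >= hold]
    pos_cores = [(a, b) for a, b in _runs(flow > hysteresis_lps) if b - a >= hold]
    if not neg_cores or not pos_cores:
        return []

    # interleave cores in time and collapse consecutive same-sign cores
    cores = sorted(
        [(a, b, -1) for a, b in neg_cores] + [(a, b, +1) for a, b in pos_cores]
    )
    merged: list[tuple[int, int, int]] = []
    for a, b, s in cores:
        if merged and merged[-1][2] == s:
            merged[-1] = (merged[-1][0], b, s)
        else:
            merged.append((a, b, s))

    nonneg = flow >= 0
    candidates: list[tuple[int, int, int]] = []  # (insp_start, insp_end, exp_core_end)
    for k, (a, b, s) in enumerate(merged):
        if s != -1 or k + 1 >= len(merged):
            continue
        pa, pb, _ = merged[k + 1]
        # walk back from the validated negative core to the zero crossing
        prior = np.flatnonzero(nonneg[:a])
        insp_start = int(prior[-1]) + 1 if len(prior) else 0
        # inspiratory end: first non-negative sample after the core
        after = np.flatnonzero(nonneg[b - 1 : pa + 1])
        insp_end = (b - 1 + int(after[0])) if len(after) else pa
        candidates.append((insp_start, insp_end, pb))

    breaths: list[BreathInterval] = []
    for k, (i0, i1, pb) in enumerate(candidates):
        if (i1 - i0) / fs < min_insp_s:
            continue
        if np.max(np.abs(flow[i0:i1])) < min_amplitude:
            continue
        if k + 1 < len(candidates):
            exp_end = candidates[k + 1][0]
        else:
            later = np.flatnonzero(flow[pb:] < 0)
            exp_end = (pb + int(later[0])) if len(later) else n
        exp_end = max(exp_end, i1)
        breaths.append(
            BreathInterval(breath_id=len(breaths), insp_start=i0, insp_end=i1, exp_end=exp_end)
        )
    return breaths


def inspired_volumes(breaths: list[BreathInterval], flow: np.ndarray, fs: float) -> np.ndarray:
    """Inspired volume per breath in liters (flow integral over inspiration)."""
    flow = np.asarray(flow, dtype=float)
    return np.array(
        [-(flow[b.insp_start : b.insp_end].sum()) / fs for b in breaths], dtype=float
    )


def detect_ic_maneuvers(
    breaths: list[BreathInterval],
    flow: np.ndarray,
    fs: float,
    method: str = "volume",
    marker_times_s: list[float] | None = None,
    volume_factor: float = 1.5,
    median_window: int = 15,
) -> list[BreathInterval]:
    """Flag IC maneuvers in place and return the breath list.

    ``marker`` mode flags breaths whose span contains an ``ic_maneuver``
    event time; ``volume`` mode flags breaths whose inspired volume
    exceeds ``volume_factor`` times a centered running median of breath
    volumes.
    """
    for b in breaths:
        b.is_ic = False
    if method == "marker":
        if marker_times_s is None:
            raise ValueError(
                "marker mode requires ic_maneuver marker times; no marker channel "
                "present - use method='volume' instead"
            )
        for tm in marker_times_s:
            idx = int(round(tm * fs))
            for b in breaths:
                if b.insp_start <= idx < b.exp_end:
                    b.is_ic = True
                    break
    elif method == "volume":
        if not breaths:
            return breaths
        vols = inspired_volumes(breaths, flow, fs)
        med = (
            pd.Series(vols)
            .rolling(median_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        for b, v, m in zip(breaths, vols, med):
            b.is_ic = bool(np.isfinite(volume_factor) and v > volume_factor * m)
    else:
        raise ValueError(f"unknown IC detection method {method!r}")
    return breaths


_PHASE_LABELS = {
    "rest_start": "rest",
    "unloaded_start": "unloaded",
    "loaded_start": "loaded",
    "test_end": "post",
}


def assign_minutes(
    breaths: list[BreathInterval],
    fs: float,
    markers=None,
    t0: float = 0.0,
) -> list[BreathInterval]:
    """Assign 1-based minute indices (half-open minutes) and phase labels.

    The minute clock starts at the ``rest_start`` marker when present,
    otherwise at ``t0`` relative to the record start.  Breaths whose onset
    precedes the clock start get ``minute_index = -1`` (excluded
    downstream).  A breath starting exactly on a minute boundary belongs
    to the later minute.
    """
    markers = markers or []
    starts = [m.time_s for m in markers if m.label == "rest_start"]
    ref = starts[0] if starts else t0
    phase_marks = sorted(
        [(m.time_s, _PHASE_LABELS[m.label]) for m in markers if m.label in _PHASE_LABELS]
    )
    for b in breaths:
        onset_s = b.insp_start / fs
        rel = onset_s - ref
        b.minute_index = int(rel // 60.0) + 1 if rel >= 0 else -1
        phase = "test"
        for tm, label in phase_marks:
            if onset_s >= tm:
                phase = label
        b.phase = phase
    return breaths


def exclude_outlier_breaths(
    breaths: list[BreathInterval],
    envelope,
    fs: float,
    min_insp_s: float = 0.3,
    z_max: float = 4.0,
) -> list[BreathInterval]:
    """Label short or noisy non-IC breaths (pure labeling; nothing removed).

    ``excluded_short``: inspiratory duration below ``min_insp_s``.
    ``excluded_noisy``: breath-mean envelope more than ``z_max`` robust
    z-scores (median/MAD) from the other breaths of its minute.
    """
    env = np.asarray(envelope, dtype=float)
    tidal = [b for b in breaths if not b.is_ic]
    for b in tidal:
        b.quality = QUALITY_OK
        if b.ti_s(fs) < min_insp_s:
            b.quality = QUALITY_SHORT
    by_minute: dict[int | None, list[BreathInterval]] = {}
    for b in tidal:
        if b.quality == QUALITY_OK:
            by_minute.setdefault(b.minute_index, []).append(b)
    for group in by_minute.values():
        if len(group) < 3:
            continue
        means = np.array([env[b.insp_start : b.insp_end].mean() for b in group])
        med = np.median(means)
        mad = np.median(np.abs(means - med))
        if mad == 0:
            continue
        z = 0.6745 * (means - med) / mad
        for b, zb in zip(group, z):
            if abs(zb) > z_max:
                b.quality = QUALITY_NOISY
    return breaths


def breaths_to_frame(breaths: list[BreathInterval], fs: float) -> pd.DataFrame:
    """Per-breath table with times in seconds (CSV-ready)."""
    return pd.DataFrame(
        {
            "breath_id": [b.breath_id for b in breaths],
            "insp_start_s": [b.insp_start / fs for b in breaths],
            "insp_end_s": [b.insp_end / fs for b in breaths],
            "exp_end_s": [b.exp_end / fs for b in breaths],
            "minute_index": [b.minute_index for b in breaths],
            "phase": [b.phase for b in breaths],
            "is_ic": [b.is_ic for b in breaths],
            "quality": [b.quality for b in breaths],
        }
    )


def breaths_from_frame(frame: pd.DataFrame, fs: float) -> list[BreathInterval]:
    """Inverse of :func:`breaths_to_frame` (used by the CLI)."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            BreathInterval(
                breath_id=int(row.breath_id),
                insp_start=int(round(row.insp_start_s * fs)),
                insp_end=int(round(row.insp_end_s * fs)),
                exp_end=int(round(row.exp_end_s * fs)),
                is_ic=bool(row.is_ic),
                minute_index=None if pd.isna(row.minute_index) else int(row.minute_index),
                phase=str(row.phase),
                quality=str(row.quality),
            )
        )
    return out
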