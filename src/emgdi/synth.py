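"""Synthetic multi-channel respiratory EMG recordings with ground truth.

Generates time-synchronized channels emulating an esophageal multipair
recording during a cycling test: five EMG channels (band-limited Gaussian
carriers gated by an inspiratory envelope, with a spatial gain profile
whose outer channels are largest), a reference ECG (fixed QRS template
train with P/T deflections at a possibly ramping heart rate), and a smooth
biphasic flow signal (negative = inspiration).  ECG couples into every EMG
channel through a channel-specific short FIR kernel; white sensor noise is
added on top.  Inspiratory-capacity (IC) maneuvers are inserted as breaths
with larger, faster inspirations at full activation.

The returned :class:`GroundTruth` carries everything property tests need:
the artifact-free EMG, the coupled-artifact and noise components, breath
boundaries, R-peak positions, and the activation values a perfect analysis
chain would measure (computed from the clean signals with the same RMS
window the pipeline uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter, sosfiltfilt

from .io import EventMarker, Recording
from .preprocess import rms_envelope

__all__ = ["SynthConfig", "GroundTruth", "simulate_recording", "simulate_ecg", "default_ic_schedule"]

# QRS template: (amplitude rel. R, center offset s, gaussian sigma s).
# Dominant energy sits below 100 Hz; the P and T deflections are the
# "residual interference" the between-QRS manual method does not blank.
_ECG_WAVES = (
    (0.18, -0.16, 0.030),  # P
    (-0.12, -0.030, 0.010),  # Q
    (1.00, 0.0, 0.012),  # R
    (-0.22, 0.030, 0.010),  # S
    (0.20, 0.22, 0.050),  # T
)

# ECG couples into the EMG channels strongly enough that, after the 20 Hz
# high-pass, the artifact is comparable to (or larger than) resting EMG and
# smaller than end-exercise EMG - as in real esophageal recordings, where
# the raw trace is dominated by the R deflections.
_DEFAULT_COUPLING_BASE = np.array([0.5, 0.3, -0.15, 0.05])
_DEFAULT_COUPLING_GAINS = (7.0, 8.0, 9.0, 8.0, 7.0)


def default_ic_schedule(duration_s: float, rest_s: float = 60.0) -> tuple[float, ...]:
    """IC maneuvers mid-minute: every rest minute, every other exercise minute."""
    times = []
    n_rest_min = int(rest_s // 60)
    for k in range(n_rest_min):
        times.append(60.0 * k + 30.0)
    minute = n_rest_min
    while 60.0 * minute + 30.0 < duration_s - 5.0:
        times.append(60.0 * minute + 30.0)
        minute += 2
    return tuple(times)


@dataclass(frozen=True)
class SynthConfig:
    """Simulation settings; identical config + seed gives bit-identical output.

    ``breath_rate_bpm`` and ``hr_bpm`` may be a scalar or a ``(start, end)``
    pair ramped linearly over the record.  ``activation_profile`` gives the
    tidal envelope amplitude (fraction of maximal, per minute from t=0);
    IC maneuvers always activate at 1.0.
    """

    duration_s: float = 480.0
    fs: float = 1000.0
    breath_rate_bpm: float | tuple[float, float] = (20.0, 30.0)
    hr_bpm: float | tuple[float, float] = (80.0, 124.0)
    hb_per_insp_target: float | None = None
    envelope_shape: str = "flat"  # flat | late_peak | early_peak
    envelope_slope: float = 2.0
    channel_gains: tuple[float, ...] = (1.0, 0.7, 0.3, 0.7, 1.0)
    ecg_coupling: tuple | None = None  # per-channel FIR kernels; None = defaults
    emg_band: tuple[float, float] = (20.0, 250.0)
    noise_sd: float = 0.001
    emg_scale_v: float = 0.15
    ecg_amp_v: float = 0.5
    tidal_volume_l: float = 0.8
    ic_volume_factor: float = 2.5
    ic_ti_factor: float = 0.8
    ti_fraction: float = 0.35
    breath_jitter: float = 0.03
    activation_profile: tuple[float, ...] = (
        0.2, 0.2, 0.2, 0.35, 0.45, 0.55, 0.6, 0.65,
    )
    ic_schedule: tuple[float, ...] | None = None
    rest_s: float = 180.0
    unloaded_s: float = 0.0
    rms_window_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 2 * self.emg_band[1]:
            raise ValueError(
                f"fs={self.fs} must exceed 2 x emg_band.high={2 * self.emg_band[1]} (Nyquist)"
            )
        if any(g < 0 for g in self.channel_gains):
            raise ValueError("channel gains must be >= 0")
        if len(self.activation_profile) == 0:
            raise ValueError("activation_profile must not be empty")
        if any(not 0 < a <= 1 for a in self.activation_profile):
            raise ValueError("activation_profile values must lie in (0, 1]")
        if self.envelope_shape not in ("flat", "late_peak", "early_peak"):
            raise ValueError(f"unknown envelope_shape {self.envelope_shape!r}")

    def ramp(self, values: float | tuple[float, float], t: np.ndarray) -> np.ndarray:
        """Evaluate a possibly-ramped parameter at times ``t`` (seconds)."""
        if np.isscalar(values):
            return np.full_like(np.asarray(t, dtype=float), float(values))
        lo, hi = values
        return lo + (hi - lo) * np.clip(np.asarray(t, dtype=float) / self.duration_s, 0, 1)

    def effective_hr(self, t: np.ndarray) -> np.ndarray:
        if self.hb_per_insp_target is not None:
            return self.hb_per_insp_target * self.ramp(self.breath_rate_bpm, t)
        return self.ramp(self.hr_bpm, t)

    def coupling_kernels(self) -> list[np.ndarray]:
        if self.ecg_coupling is not None:
            return [np.asarray(k, dtype=float) for k in self.ecg_coupling]
        return [g * _DEFAULT_COUPLING_BASE for g in _DEFAULT_COUPLING_GAINS]

    def activation_at_minute(self, minute0: int) -> float:
        """Activation for a 0-based minute; the last value extends onward."""
        idx = min(max(minute0, 0), len(self.activation_profile) - 1)
        return self.activation_profile[idx]


@dataclass
class GroundTruth:
    """Everything a perfect analysis would know about one simulation."""

    fs: float
    clean_emg: dict[str, np.ndarray]
    ecg_artifact: dict[str, np.ndarray]
    noise: dict[str, np.ndarray]
    breath_onsets: np.ndarray  # inspiratory onsets, sample indices
    insp_ends: np.ndarray
    breath_offsets: np.ndarray  # expiratory ends (half-open)
    is_ic: np.ndarray
    breath_minutes: np.ndarray  # 1-based minute of each breath onset
    r_peaks: np.ndarray
    true_emgdimax: dict[str, float]
    true_activation_per_minute: dict[int, float]  # ratio in (0, 1]
    best_channel: str
    breath_true_ratio: np.ndarray = field(default=None)  # per tidal breath; NaN for ICs

    def __post_init__(self) -> None:
        on, ie, off = self.breath_onsets, self.insp_ends, self.breath_offsets
        if not (np.all(on < ie) and np.all(ie <= off)):
            raise ValueError("breath intervals must satisfy onset < insp_end <= exp_end")
        if np.any(off[:-1] > on[1:]):
            raise ValueError("breath intervals must be disjoint and ordered")

    def true_minute_activation(
        self, channel: str, rms_window_s: float = 0.05
    ) -> dict[int, float]:
        """Per-minute activation ratio a perfect analyzer of ``channel``
        would measure from the artifact-free signal."""
        env = rms_envelope(self.clean_emg[channel], self.fs, rms_window_s).values
        peaks = [
            env[a:b].max()
            for a, b, ic in zip(self.breath_onsets, self.insp_ends, self.is_ic)
            if ic
        ]
        if not peaks:
            raise ValueError("no IC maneuver in the simulation")
        ref = max(peaks)
        out: dict[int, float] = {}
        for m in np.unique(self.breath_minutes):
            sel = (self.breath_minutes == m) & ~self.is_ic
            if sel.any():
                means = [
                    env[a:b].mean()
                    for a, b in zip(self.breath_onsets[sel], self.insp_ends[sel])
                ]
                out[int(m)] = float(np.mean(means) / ref)
        return out


def simulate_ecg(
    hr_profile: float | tuple[float, float] | np.ndarray,
    fs: float,
    n_samples: int | None = None,
    amplitude: float = 1.0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-template QRS train (with P/T waves) at an instantaneous rate.

    ``hr_profile`` may be a scalar (bpm), a ``(start, end)`` ramp over the
    record, or a per-sample array.  Returns ``(signal, r_peak_indices)``.
    """
    if n_samples is None:
        if hasattr(hr_profile, "__len__") and not isinstance(hr_profile, tuple):
            n_samples = len(hr_profile)
        elif duration_s is not None:
            n_samples = int(round(duration_s * fs))
        else:
            raise ValueError("n_samples or duration_s required for non-array hr_profile")
    t = np.arange(n_samples) / fs
    if np.isscalar(hr_profile):
        hr = np.full(n_samples, float(hr_profile))
    elif isinstance(hr_profile, tuple):
        lo, hi = hr_profile
        hr = lo + (hi - lo) * t / (n_samples / fs)
    else:
        hr = np.asarray(hr_profile, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hr_profile must be positive everywhere")
    if np.any(hr / 60.0 > fs):
        raise ValueError(f"heart rate exceeds the fs-resolvable rate ({fs * 60:.0f} bpm)")

    phase = np.cumsum(hr / 60.0) / fs  # beats elapsed
    total = phase[-1]
    beat_marks = np.arange(0.4, total, 1.0)
    r_peaks = np.searchsorted(phase, beat_marks)
    r_peaks = r_peaks[r_peaks < n_samples]

    half_pre, half_post = int(round(0.30 * fs)), int(round(0.35 * fs))
    offs = np.arange(-half_pre, half_post + 1)
    template = np.zeros_like(offs, dtype=float)
    for amp, center, sigma in _ECG_WAVES:
        template += amp * np.exp(-0.5 * ((offs / fs - center) / sigma) ** 2)
    template *= amplitude

    signal = np.zeros(n_samples)
    for r in r_peaks:
        lo = r - half_pre
        hi = r + half_post + 1
        tl = max(0, -lo)
        th = len(offs) - max(0, hi - n_samples)
        signal[max(lo, 0) : min(hi, n_samples)] += template[tl:th]
    return signal, r_peaks


def _envelope_core(tau: np.ndarray, kind: str, slope: float) -> np.ndarray:
    """Within-inspiration envelope on tau in [0, 1], peak 1.

    ``flat`` is a level plateau; ``late_peak`` rises toward end-inspiration
    (power law controlled by ``slope``), ``early_peak`` is its mirror.
    Activation leads flow onset and outlasts it slightly, so the on/off
    transients live *outside* this core (see the gate construction).
    """
    floor = 0.15
    if kind == "flat":
        return np.ones_like(tau)
    if kind == "late_peak":
        return floor + (1.0 - floor) * np.power(np.clip(tau, 0, 1), slope)
    if kind == "early_peak":
        return floor + (1.0 - floor) * np.power(np.clip(1.0 - tau, 0, 1), slope)
    raise ValueError(kind)  # pragma: no cover - validated in SynthConfig


def _band_carrier(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, white)
    return x / np.sqrt(np.mean(x**2))


def simulate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.

    Channels: ``emg_1`` .. ``emg_5`` (volts), ``ecg`` (volts), ``flow``
    (L/s, negative = inspiration).  Each EMG channel is
    ``gain * scale * envelope(t) * carrier + coupling * ecg + noise``.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    seeds = np.random.SeedSequence(config.seed).spawn(12)
    rng_breath = np.random.default_rng(seeds[0])
    rng_carriers = [np.random.default_rng(seeds[1 + c]) for c in range(5)]
    rng_noise = [np.random.default_rng(seeds[6 + c]) for c in range(5)]

    # ---- breath schedule and flow / envelope-gate construction ----------
    ic_times = list(
        config.ic_schedule
        if config.ic_schedule is not None
        else default_ic_schedule(config.duration_s, config.rest_s)
    )
    flow = np.zeros(n)
    gate = np.zeros(n)
    onsets, insp_ends, offsets, ic_flags, minutes = [], [], [], [], []
    breath_ratio = []
    t = 0.0
    ic_ptr = 0
    while True:
        rate = float(config.ramp(config.breath_rate_bpm, np.array([t]))[0])
        period = 60.0 / rate
        period *= 1.0 + config.breath_jitter * float(rng_breath.uniform(-1, 1))
        is_ic = ic_ptr < len(ic_times) and t <= ic_times[ic_ptr] < t + period
        ti = config.ti_fraction * period
        volume = config.tidal_volume_l
        if is_ic:
            ti *= config.ic_ti_factor
            volume *= config.ic_volume_factor
            ic_ptr += 1
        te = period - ti
        i0 = int(round(t * fs))
        i1 = int(round((t + ti) * fs))
        i2 = int(round((t + period) * fs))
        if i2 > n or i1 >= n:
            break
        minute0 = int(t // 60.0)
        amp = 1.0 if is_ic else config.activation_at_minute(minute0)

        amp_insp = np.pi * volume / (2.0 * ti)
        tau_i = np.arange(i0, i1)
        flow[i0:i1] = -amp_insp * np.sin(np.pi * (tau_i - i0) / max(i1 - i0, 1))
        amp_exp = amp_insp * ti / te
        tau_e = np.arange(i1, i2)
        flow[i1:i2] = amp_exp * np.sin(np.pi * (tau_e - i1) / max(i2 - i1, 1))

        tau = (tau_i - i0) / max(i1 - i0 - 1, 1)
        core = _envelope_core(tau, config.envelope_shape, config.envelope_slope)
        gate[i0:i1] = np.maximum(gate[i0:i1], amp * core)
        # neural drive leads flow onset and decays after inspiration ends
        lead = min(int(round(0.08 * fs)), i0)
        if lead > 0:
            rise = 0.5 * (1 - np.cos(np.pi * np.arange(lead) / lead))
            gate[i0 - lead : i0] = np.maximum(
                gate[i0 - lead : i0], amp * core[0] * rise
            )
        fall_n = min(int(round(0.12 * fs)), n - i1)
        if fall_n > 0:
            fall = 0.5 * (1 + np.cos(np.pi * np.arange(fall_n) / fall_n))
            gate[i1 : i1 + fall_n] = np.maximum(
                gate[i1 : i1 + fall_n], amp * core[-1] * fall
            )

        onsets.append(i0)
        insp_ends.append(i1)
        offsets.append(i2)
        ic_flags.append(is_ic)
        minutes.append(minute0 + 1)
        breath_ratio.append(np.nan if is_ic else amp)
        t += period

    onsets = np.array(onsets, dtype=int)
    insp_ends = np.array(insp_ends, dtype=int)
    offsets = np.array(offsets, dtype=int)
    ic_flags = np.array(ic_flags, dtype=bool)
    minutes = np.array(minutes, dtype=int)

    # ---- ECG and channel mixing ----------------------------------------
    hr = config.effective_hr(np.arange(n) / fs)
    ecg, r_peaks = simulate_ecg(hr, fs, n_samples=n, amplitude=config.ecg_amp_v)
    kernels = config.coupling_kernels()

    clean, artifact, noise_d = {}, {}, {}
    channels: dict[str, np.ndarray] = {}
    gains = config.channel_gains
    for c in range(5):
        name = f"emg_{c + 1}"
        carrier = _band_carrier(n, fs, config.emg_band, rng_carriers[c])
        clean[name] = gains[c] * config.emg_scale_v * gate * carrier
        artifact[name] = lfilter(kernels[c], [1.0], ecg)
        noise_d[name] = (
            config.noise_sd * rng_noise[c].standard_normal(n)
            if config.noise_sd > 0
            else np.zeros(n)
        )
        channels[name] = clean[name] + artifact[name] + noise_d[name]
    channels["ecg"] = ecg
    channels["flow"] = flow

    markers = [EventMarker(0.0, "rest_start")]
    if config.unloaded_s > 0:
        markers.append(EventMarker(config.rest_s, "unloaded_start"))
    markers.append(EventMarker(config.rest_s + config.unloaded_s, "loaded_start"))
    for tt in ic_times[:ic_ptr]:
        markers.append(EventMarker(tt, "ic_maneuver"))
    markers.append(EventMarker(config.duration_s, "test_end"))
    markers.sort(key=lambda m: m.time_s)
    recording = Recording(fs=fs, channels=channels, markers=markers)

    # ---- ground-truth measurands (clean-signal analysis) ----------------
    best_idx = int(np.argmax(gains))
    best = f"emg_{best_idx + 1}"
    env_clean = {
        name: rms_envelope(sig, fs, config.rms_window_s).values for name, sig in clean.items()
    }
    true_max = {}
    for name, env in env_clean.items():
        peaks = [env[a:b].max() for a, b, ic in zip(onsets, insp_ends, ic_flags) if ic]
        true_max[name] = float(max(peaks)) if peaks else float("nan")

    breath_true = np.full(len(onsets), np.nan)
    if np.isfinite(true_max.get(best, np.nan)):
        for k, (a, b, ic) in enumerate(zip(onsets, insp_ends, ic_flags)):
            if not ic:
                breath_true[k] = env_clean[best][a:b].mean() / true_max[best]
    per_minute: dict[int, float] = {}
    for m in np.unique(minutes):
        sel = (minutes == m) & ~ic_flags
        if sel.any() and np.isfinite(breath_true[sel]).any():
            per_minute[int(m)] = float(np.nanmean(breath_true[sel]))

    truth = GroundTruth(
        fs=fs,
        clean_emg=clean,
        ecg_artifact=artifact,
        noise=noise_d,
        breath_onsets=onsets,
        insp_ends=insp_ends,
        breath_offsets=offsets,
        is_ic=ic_flags,
        breath_minutes=minutes,
        r_peaks=r_peaks,
        true_emgdimax=true_max,
        true_activation_per_minute=per_minute,
        best_channel=best,
        breath_true_ratio=breath_true,
    )
    return recording, truth
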