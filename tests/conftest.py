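"""Shared fixtures: simulated recordings are expensive, so the default
scenario is session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from emgdi.synth import SynthConfig, simulate_recording


@pytest.fixture(scope="session")
def default_sim():
    """Default 8-minute scenario (flat envelope, HR ramp 80->124)."""
    return simulate_recording(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """Short scenario for cheap tests (2 min, 2 ICs)."""
    cfg = SynthConfig(
        duration_s=120.0,
        rest_s=60.0,
        activation_profile=(0.25, 0.5),
        seed=3,
    )
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def segmented_default(default_sim):
    from emgdi.cli import segment_recording

    rec, truth = default_sim
    return rec, truth, segment_recording(rec)


def expiratory_mask(truth, fs, n, settle_s=0.2, after_s=30.0):
    """Quiet expiratory samples (past the envelope decay), after ``after_s``."""
    mask = np.zeros(n, dtype=bool)
    for b, e in zip(truth.insp_ends, truth.breath_offsets):
        lo = b + int(settle_s * fs)
        if lo < e and b / fs > after_s:
            mask[lo:e] = True
    return mask


def inspiratory_mask(truth, fs, n, after_s=30.0):
    mask = np.zeros(n, dtype=bool)
    for a, b in zip(truth.breath_onsets, truth.insp_ends):
        if a / fs > after_s:
            mask[a:b] = True
    return mask
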