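"""Shared fixtures: synthetic events and recordings, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from vaneedle.event_analysis import compute_cwt, segment_phases
from vaneedle.preprocessing import preprocess
from vaneedle.synthetic_data import SimEventConfig, simulate_event, simulate_insertion


@pytest.fixture(scope="session")
def default_event():
    """One default cavity-event segment with its ground truth (seed 1)."""
    return simulate_event(seed=1)


@pytest.fixture(scope="session")
def processed_event(default_event):
    seg, truth = default_event
    return preprocess(seg), truth


@pytest.fixture(scope="session")
def segmented_event(processed_event):
    seg, truth = processed_event
    bounds = segment_phases(seg, compute_cwt(seg))
    return seg, truth, bounds


@pytest.fixture(scope="session")
def cavity_insertion():
    """A full insertion recording containing one cavity event (seed 3)."""
    return simulate_insertion(seed=3, reached_cavity=True, duration_s=8.0)


@pytest.fixture(scope="session")
def noise_only_recording():
    """Background noise with the default RMS and no events at all."""
    from vaneedle.signal_io import Recording

    rng = np.random.default_rng(99)
    cfg = SimEventConfig()
    return Recording(rng.normal(0.0, cfg.noise_rms, 8 * 16000), 16000.0, "noise")
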