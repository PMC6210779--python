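"""Shared fixtures: synthetic walks pushed through the detection chain."""

import numpy as np
import pytest

from kneegait.events import find_initial_contacts
from kneegait.parameters import summarize_gait
from kneegait.signal_core import lowpass_filter, realign_to_horizontal_vertical
from kneegait.simulate import WalkSimulationSpec, simulate_walk


def detect_walk(spec):
    """simulate -> realign -> filter -> detect; returns (rec, truth, corrected, ics)."""
    rec, truth = simulate_walk(spec)
    corrected = realign_to_horizontal_vertical(rec)
    filtered = lowpass_filter(corrected.vertical, rec.sampling_rate)
    ics = find_initial_contacts(filtered, rec.sampling_rate, side=rec.side,
                                source_id=rec.subject_id)
    return rec, truth, corrected, ics


def recover_summary(spec):
    """Full single-leg pipeline on one synthetic walk."""
    rec, truth, corrected, ics = detect_walk(spec)
    summary, records = summarize_gait(ics, corrected.vertical, rec.sampling_rate)
    return truth, summary, records, ics


def match_events(true_times, detected_times, tol_samples, fs=32.0):
    """(n matched within tol, worst error in samples, n spurious beyond 2 samples)."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    if detected_times.size == 0:
        return 0, np.inf, 0
    errs = np.array([np.min(np.abs(detected_times - t)) * fs for t in true_times])
    spurious = int(np.sum([np.min(np.abs(true_times - d)) * fs > 2.0001 for d in detected_times]))
    return int(np.sum(errs <= tol_samples + 1e-4)), float(errs.max()), spurious


@pytest.fixture(scope="session")
def clean_walk():
    """A deterministic, noise-free 30-step walk with uniform timing."""
    spec = WalkSimulationSpec(
        n_steps=30, step_time_mean=0.53, step_time_sd=0.0,
        D_mean=0.008, D_sd=0.0, noise_sd=0.0, seed=1,
    )
    return detect_walk(spec)
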