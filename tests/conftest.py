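"""Shared fixtures: synthetic trials at several noise levels.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from bowfreeze.io import REQUIRED_ROLES, TrialRecording
from bowfreeze.simulate import preset, simulate_trial


def make_static_trial(n_frames: int = 20, rate_hz: float = 60.0) -> TrialRecording:
    """A motionless but geometrically valid trial (zero-amplitude profile)."""
    profile = replace(
        preset("novice_like"), shoulder_amp=0.0, joint_noise_sd=0.0, marker_noise_sd=0.0
    )
    trial, _ = simulate_trial(profile, n_cycles=1, rate_hz=rate_hz, seed=0, pad_s=0.0)
    trial.positions = trial.positions[:n_frames]
    trial.missing = trial.missing[:n_frames]
    return trial


@pytest.fixture(scope="session")
def novice_clean():
    """Noise-free shoulder-only trial with ground truth."""
    profile = replace(preset("novice_like"), joint_noise_sd=0.0, marker_noise_sd=0.0)
    return simulate_trial(profile, seed=11)


@pytest.fixture(scope="session")
def expert_clean():
    """Noise-free expert-style trial (shoulder+elbow transport, wrist gains)."""
    profile = replace(preset("expert_like"), joint_noise_sd=0.0, marker_noise_sd=0.0)
    return simulate_trial(profile, seed=12)


@pytest.fixture(scope="session")
def expert_noisy():
    return simulate_trial(preset("expert_like"), seed=13)


@pytest.fixture()
def static_trial():
    return make_static_trial()


@pytest.fixture()
def tiny_trial():
    """Minimal hand-built 3-frame trial covering all required roles."""
    rng = np.random.default_rng(0)
    labels = list(REQUIRED_ROLES)
    positions = rng.uniform(-500, 500, size=(3, len(labels), 3))
    return TrialRecording(
        positions=positions,
        rate_hz=60.0,
        labels=labels,
        roles={r: r for r in labels},
        meta={"participant_id": "p1", "group": "novice", "lab": "A"},
    )
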