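"""Shared fixtures: small synthetic protocols sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from emofc.containers import HVA, LVA
from emofc.montage import FRONTAL_8
from emofc.preprocess import segment_and_baseline
from emofc.synthetic import PlantSpec, ProtocolConfig, generate_dataset, generate_subject

#: a compact montage for tests that do not need all 32 electrodes
SMALL_LABELS = ("Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "Pz", "M1", "M2")


@pytest.fixture(scope="session")
def small_cfg() -> ProtocolConfig:
    return ProtocolConfig(
        n_subjects=2, n_trials_per_class=3, rest_s=2.0, stim_s=5.0, fs=200.0,
        channel_labels=SMALL_LABELS, seed=11,
    )


@pytest.fixture(scope="session")
def small_plant() -> PlantSpec:
    return PlantSpec(
        discriminative_channels=("Fp1", "Fp2", "F7"),
        coherent_pairs=[("Fp1", "Fp2", {HVA: 0.25, LVA: 0.35})],
    )


@pytest.fixture(scope="session")
def small_recording(small_cfg, small_plant):
    return generate_subject(small_cfg, small_plant, subject_id=0)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_plant):
    return generate_dataset(small_cfg, small_plant)


@pytest.fixture(scope="session")
def small_segments(small_recording, small_cfg):
    return segment_and_baseline(small_recording, stim_s=small_cfg.stim_s, baseline_s=small_cfg.rest_s)


def sine_recording(freq_hz: float, fs: float = 500.0, dur_s: float = 12.0, n_ch: int = 2):
    """A deterministic pure-tone recording used by the filter tests."""
    from emofc.containers import EEGRecording

    t = np.arange(int(dur_s * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_ch, 1)) * 50.0
    return EEGRecording(data=data, fs=fs, labels=tuple(f"C{i}" for i in range(n_ch)))
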