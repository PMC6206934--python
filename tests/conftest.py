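"""Shared fixtures: small synthetic subjects generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from plvdecode import connectivity as conn
from plvdecode import preprocess as pp
from plvdecode import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(**overrides) -> sd.SimulationConfig:
    defaults = dict(n_channels=8, n_trials_per_class=3, rest_length=40.0,
                    n_rest_trials=5, seed=11)
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset() -> sd.StudyDataset:
    """An 8-channel, 3-trials-per-class subject for cheap structural tests."""
    return sd.make_study_dataset(tiny_config())


def recovery_schedule(n_channels: int, window=(0.5, 4.0), kappa: float = 0.8,
                      jitter: float = 0.1, snr_db: float = 10.0,
                      pairs_per_class: int = 4) -> sd.CouplingSchedule:
    """Class-dependent couplings on channel-disjoint index pairs."""
    entries = []
    for band in ("alpha1", "beta1"):
        for j in range(pairs_per_class):
            entries.append(sd.CouplingEntry(
                (n_channels - 1 - 2 * j, n_channels - 2 - 2 * j), band,
                "left", window, kappa))
            entries.append(sd.CouplingEntry((2 * j, 2 * j + 1), band,
                                            "right", window, kappa))
    return sd.CouplingSchedule(entries=entries, jitter_sd=jitter, snr_db=snr_db)


@pytest.fixture(scope="session")
def recovery_dataset() -> sd.StudyDataset:
    """The planted-coupling recovery subject: kappa=0.8, 10 dB SNR,
    20 trials per class, 16 channels."""
    config = sd.SimulationConfig(n_channels=16, n_trials_per_class=20,
                                 rest_length=180.0, n_rest_trials=20,
                                 schedule=recovery_schedule(16), seed=7)
    return sd.make_study_dataset(config)


def band_trials(dataset: sd.StudyDataset, band: str, window=(0.0, 5.0)):
    """Preprocess one subject's MI recording and split epochs by class."""
    rec = pp.prepare_continuous(dataset.mi_recording, band)
    trials = pp.segment(rec, window=window)
    left = trials.trials[[i for i, l in enumerate(trials.labels) if l == "left"]]
    right = trials.trials[[i for i, l in enumerate(trials.labels) if l == "right"]]
    return left, right, trials.fs


@pytest.fixture(scope="session")
def recovery_band_trials(recovery_dataset):
    """beta1-filtered left/right epochs of the recovery subject."""
    return band_trials(recovery_dataset, "beta1")


@pytest.fixture(scope="session")
def recovery_sequences(recovery_band_trials):
    """Cued-decoding sequences (350 ms step) of the recovery subject."""
    left, right, fs = recovery_band_trials
    Ls = np.stack([conn.sliding_connectivity(t, fs, "beta1", 0.35).vecs
                   for t in left])
    Rs = np.stack([conn.sliding_connectivity(t, fs, "beta1", 0.35).vecs
                   for t in right])
    return Ls, Rs
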