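"""Shared fixtures: small synthetic datasets and toy builders."""

from __future__ import annotations

import numpy as np
import pytest

from rpbci.core import EpochSet, TrialRecord
from rpbci.preprocess import downsample
from rpbci.simulate import SimConfig, epochs_from_trials, simulate_dataset


def make_epochset(
    rng: np.random.Generator,
    n_per_class: dict[str, int],
    n_channels: int = 4,
    n_samples: int = 20,
    fs: float = 100.0,
    with_eog: bool = False,
    class_shift: float = 0.0,
) -> EpochSet:
    """Random EpochSet; ``class_shift`` adds a label-dependent offset on
    channel 0 so classes become separable when needed."""
    data, labels = [], []
    shift = {"R": 1.0, "I": 0.0, "L": -1.0}
    for lab, n in n_per_class.items():
        for _ in range(n):
            x = rng.standard_normal((n_channels, n_samples))
            x[0] += class_shift * shift[lab]
            data.append(x)
            labels.append(lab)
    data = np.stack(data)
    eog = rng.standard_normal((len(labels), 2, n_samples)) if with_eog else None
    return EpochSet(
        data=data,
        labels=np.array(labels, dtype=object),
        channel_names=[f"ch{i}" for i in range(n_channels)],
        fs=fs,
        eog=eog,
    )


def make_trial(
    fs: float = 100.0,
    cue_time: float = 1.0,
    press_times=(4.0,),
    cue_side: str = "R",
    duration: float = 6.0,
    trial_index: int = 0,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * fs))
    return TrialRecord(
        continuous_eeg=rng.standard_normal((3, n)),
        continuous_eog=rng.standard_normal((2, n)),
        fs=fs,
        cue_time=cue_time,
        press_times=list(press_times),
        cue_side=cue_side,
        trial_index=trial_index,
    )


#: A small but realistic simulated participant, shared across tests.
SMALL_SIM = SimConfig(n_trials_per_side=25, fs_acquire=200.0,
                      p_reactive=0.0, p_multipress=0.0, seed=11)


@pytest.fixture(scope="session")
def small_sim_dataset():
    trials, gt = simulate_dataset(SMALL_SIM)
    return trials, gt


@pytest.fixture(scope="session")
def small_sim_epochs(small_sim_dataset):
    trials, _ = small_sim_dataset
    return downsample(epochs_from_trials(trials), 100.0)
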