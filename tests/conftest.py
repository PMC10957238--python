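import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import eegability as ea
from eegability.datasets import EpochSet

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stim20():
    """10 faces + 10 nonfaces: the scaled-down study stimulus set."""
    return ea.make_stimulus_set(10, 10, seed=1)


@pytest.fixture(scope="session")
def stim49():
    """The full 49-stimulus design (24 faces, 25 nonfaces)."""
    return ea.make_stimulus_set(24, 25, seed=1)


@pytest.fixture(scope="session")
def planted_geometries(stim20):
    """Midlevel (150 ms) and semantic (650 ms) geometries coupled to
    ability, plus an uncoupled control geometry at 350 ms."""
    specs = [
        ea.GeometrySpec(
            name="midlevel_visual", kind="block", center_ms=150.0, width_ms=20.0,
            ability_coupling=0.5,
        ),
        ea.GeometrySpec(
            name="semantic", kind="category", center_ms=650.0, width_ms=50.0,
            ability_coupling=0.5,
        ),
        ea.GeometrySpec(
            name="control", kind="random", center_ms=350.0, width_ms=30.0,
            ability_coupling=0.0,
        ),
    ]
    return ea.make_latent_geometries(stim20, specs, seed=2)


@pytest.fixture(scope="session")
def coupled_cohort(stim20, planted_geometries):
    """8 super + 8 typical recognizers with planted, ability-coupled
    representational geometry (scaled-down study conditions)."""
    return ea.simulate_cohort(
        stim20,
        planted_geometries,
        n_super=8,
        n_typical=8,
        n_trials_per_participant=480,
        n_channels=16,
        sampling_rate=64.0,
        n_sessions=1,
        noise_sd=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def brain_rdms(coupled_cohort):
    """Per-participant cross-validated pairwise-decoding RDM time courses."""
    return {
        pid: ea.brain_rdm_timecourse(es, n_folds=5, n_repetitions=1, seed=13)
        for pid, es in coupled_cohort.epochs.items()
    }


@pytest.fixture(scope="session")
def typical_cohort(stim20, planted_geometries):
    """12 typical recognizers only, for continuous ability decoding."""
    return ea.simulate_cohort(
        stim20,
        planted_geometries,
        n_super=0,
        n_typical=12,
        n_trials_per_participant=200,
        n_channels=16,
        sampling_rate=64.0,
        n_sessions=1,
        noise_sd=2.0,
        seed=21,
    )


def make_epochs(
    data: np.ndarray,
    *,
    sfreq: float = 64.0,
    t0_ms: float = 0.0,
    stimulus_id=None,
    session=None,
    is_repeat=None,
    response_made=None,
) -> EpochSet:
    """Hand-build an EpochSet around a raw (trials, channels, samples) array."""
    n_trials, n_channels, n_samples = data.shape
    labels, pos = ea.hemisphere_montage(n_channels)
    trials = pd.DataFrame(
        dict(
            stimulus_id=np.zeros(n_trials, int) if stimulus_id is None else stimulus_id,
            session=np.ones(n_trials, int) if session is None else session,
            is_repeat=np.zeros(n_trials, bool) if is_repeat is None else is_repeat,
            response_made=(
                np.zeros(n_trials, bool) if response_made is None else response_made
            ),
        )
    )
    times = t0_ms + np.arange(n_samples) * 1000.0 / sfreq
    return EpochSet(data, times, sfreq, labels, pos, trials)


def make_two_group_cohort(epochs_by_pid: dict, groups: dict, abilities=None):
    """Assemble a CohortDataset from hand-built EpochSets."""
    if abilities is None:
        abilities = {
            pid: (95 if g == "super" else 70) for pid, g in groups.items()
        }
    participants = pd.DataFrame(
        [
            dict(participant_id=pid, group=groups[pid], ability=abilities[pid])
            for pid in epochs_by_pid
        ]
    )
    return ea.CohortDataset(participants=participants, epochs=dict(epochs_by_pid))
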