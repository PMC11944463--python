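import dataclasses

import pandas as pd
import pytest

import emodecode as ed


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    return ed.build_stimulus_design()


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    """2 speakers x 1 word x 4 emotions x 3 morphs + 2 averages = 26 stimuli."""
    return ed.build_stimulus_design(n_speakers=2, n_words=1)


@pytest.fixture(scope="session")
def small_config() -> ed.SimulationConfig:
    """Fast world: quieter noise, same structure as the default."""
    return dataclasses.replace(
        ed.SimulationConfig(), white_noise_sd=1.0, pink_noise_sd=2.0,
        master_seed=99)


@pytest.fixture(scope="session")
def small_subject_eeg(small_design, small_config) -> ed.EpochedEEG:
    """One simulated musician, 52 trials, raw 500 Hz epochs with EOG."""
    trials = ed.build_trial_table(small_design, n_reps=2, n_blocks=4,
                                  prompt_rate=0.10, seed=3)
    subject = ed.Subject("mus01", "musician", 17)
    return ed.simulate_subject_eeg(trials, small_design, subject, small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_subject_eeg) -> ed.EpochedEEG:
    return ed.preprocess(small_subject_eeg)
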