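"""Shared fixtures: one synthetic study session and one trained twin model.

The heavy artifacts (a ~2,300-window session and a 100-epoch twin fit) are
session-scoped so the recovery experiments and the acceptance checks share
a single training run.
"""

import numpy as np
import pytest
from hypothesis import settings

import lateralgait as lg
from lateralgait.features import feature_columns
from lateralgait.simulate import PHASES

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

STUDY_SEED = 3


@pytest.fixture(scope="session")
def study_config():
    """Default study conditions at desk scale: 10 lateral steps (~14.6 s),
    which yields ~4,800 sliding windows at 250 ms / 3 ms — enough
    independent gait cycles for held-out generalization, at a fraction of
    the full 30-step recording protocol."""
    return lg.SimulationConfig(n_steps=10, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def session_recording(study_config):
    return lg.simulate_session(study_config)


@pytest.fixture(scope="session")
def synced(session_recording):
    return lg.synchronize(session_recording)


@pytest.fixture(scope="session")
def labels(synced):
    return lg.label_recording(synced.pressure, fs=synced.fs)


@pytest.fixture(scope="session")
def features_df(synced, labels):
    return lg.assemble_samples(synced, labels)


def split_frame(df, test_fraction=0.3):
    n_test = int(round(test_fraction * len(df)))
    return df.iloc[:-n_test], df.iloc[-n_test:]


def phase_codes(df):
    return np.array([PHASES.index(p) for p in df["phase"]])


@pytest.fixture(scope="session")
def trained_twin(features_df):
    """Twin model fitted at scaled-down depth (100 epochs) on a 70/30
    chronological split of the study session."""
    train_df, test_df = split_frame(features_df)
    model = lg.TwinBrotherModel.from_dataframe(
        train_df,
        elder_config=lg.ElderConfig(epochs=100, seed=STUDY_SEED),
        younger_config=lg.YoungerConfig(epochs=100, seed=STUDY_SEED))
    results = model.fit()
    return {
        "results": results,
        "train_df": train_df,
        "test_df": test_df,
        "test_X": test_df[feature_columns()].to_numpy(),
        "test_phase": phase_codes(test_df),
    }
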