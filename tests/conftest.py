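import numpy as np
import pandas as pd
import pytest

from bedpose.features import features_from_recording
from bedpose.signal import BedModel
from bedpose.simulate import generate_cohort


@pytest.fixture(scope="session")
def bed() -> BedModel:
    return BedModel()


def cohort_features(
    n: int,
    master_seed: int,
    bed: BedModel,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulate a cohort at reduced pose durations and extract features."""
    members = generate_cohort(
        n,
        bed,
        master_seed=master_seed,
        primary_duration=90.0,
        intermediate_duration=45.0,
        n_random_poses=6,
        random_pose_duration=90.0,
        noise_sd=noise_sd,
    )
    tables = []
    for m in members:
        for rec in (m.phase_one, m.phase_two):
            tables.append(features_from_recording(rec, bed))
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def small_cohort(bed) -> pd.DataFrame:
    """Six-participant feature table shared across classifier tests."""
    return cohort_features(6, master_seed=1, bed=bed)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
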