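import numpy as np
import pandas as pd
import pytest

from funcgeo import synthetic as syn
from funcgeo.types import Recording

GAMMA_ONLY = (("gamma", 30.0, 50.0),)


def make_recording(data: np.ndarray, fs: float) -> Recording:
    n = data.shape[0]
    meta = pd.DataFrame({
        "participant": [0] * n,
        "roi": [f"R{i}" for i in range(n)],
        "hemisphere": ["L"] * n,
    })
    return Recording(data=data, fs=fs, channel_meta=meta)


@pytest.fixture(scope="session")
def tiny_config() -> syn.CohortConfig:
    """Small two-community cohort used across modules (3 participants,
    6 ROIs, 150 s at 250 Hz, gamma carriers only)."""
    return syn.CohortConfig(n_participants=3, n_rois=6,
                            sites_per_roi=(1, 2), fs=250.0, duration=150.0,
                            bands=GAMMA_ONLY, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return syn.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_recording(tiny_cohort) -> Recording:
    return tiny_cohort[0][0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
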