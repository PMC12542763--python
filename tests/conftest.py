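import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from holomics.simulate import SimulationConfig, simulate_feature_table
from holomics.tables import FeatureTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but complete simulated study: all artifact classes present."""
    return SimulationConfig(
        n_true_features=40,
        artifact_counts={c: 8 for c in ("ringing", "isotopologue", "insource",
                                        "blank_contaminant", "high_cv")},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_feature_table(small_config)


def make_table(intensities: dict, mz, rt, meta_rows: dict) -> FeatureTable:
    """Hand-build a FeatureTable from plain dicts (helper for worked examples)."""
    frame = pd.DataFrame(intensities).T.astype(float)
    meta = pd.DataFrame(meta_rows).T
    meta.index.name = "column"
    meta.columns = ["sample", "group", "replicate"]
    return FeatureTable(
        frame,
        pd.Series(mz, index=frame.index, dtype=float, name="mz"),
        pd.Series(rt, index=frame.index, dtype=float, name="rt"),
        meta,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
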