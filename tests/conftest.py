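import numpy as np
import pandas as pd
import pytest

from netstab import SynthConfig, generate_dataset
from netstab.network import FeatureTable


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """A fast two-group cohort: 3+3 subjects, 6 two-second epochs each."""
    return SynthConfig(
        n_subjects_per_group={"P": 3, "HC": 3},
        n_epochs_per_subject=6,
        kappa_group={"P": 1.0, "HC": 6.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def toy_table() -> FeatureTable:
    """Separable subject-level table: one informative column, three noise."""
    rng = np.random.default_rng(0)
    n_per = 10
    labels = ["P"] * n_per + ["HC"] * n_per
    signal = np.r_[rng.normal(2.0, 0.4, n_per), rng.normal(-2.0, 0.4, n_per)]
    feats = pd.DataFrame(
        {
            "signal": signal,
            "noise_a": rng.normal(size=2 * n_per),
            "noise_b": rng.normal(size=2 * n_per),
            "constant": np.ones(2 * n_per),
        }
    )
    subjects = pd.Series([f"S{i:02d}" for i in range(2 * n_per)], name="subject_id")
    return FeatureTable(feats, pd.Series(labels, name="label"), subjects)
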