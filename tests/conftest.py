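import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from swimfatigue import PopulationConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def noiseless_config() -> PopulationConfig:
    """Point-mass energy and length: every trial at a velocity is identical."""
    return PopulationConfig(energy_dist="point", energy_logsd=0.0,
                            length_sd=0.0, length_min=4.0, length_max=6.0)


@pytest.fixture
def default_config() -> PopulationConfig:
    return PopulationConfig()


def make_trials(lengths, U_f=None, T_f=None, success=None,
                species="sp") -> pd.DataFrame:
    """Hand-built trials table for analysis-stage tests."""
    n = len(lengths)
    lengths = np.asarray(lengths, dtype=float)
    U_f = np.full(n, 50.0) if U_f is None else np.asarray(U_f, dtype=float)
    T_f = np.full(n, 10.0) if T_f is None else np.asarray(T_f, dtype=float)
    success = np.ones(n, bool) if success is None else np.asarray(success, bool)
    return pd.DataFrame({
        "species": species,
        "fish_id": np.arange(n),
        "fork_length": lengths,
        "body_depth": 0.22 * lengths,
        "mass": 0.0135 * lengths**3,
        "U_f": U_f,
        "temperature": 13.4,
        "T_f": np.where(success, T_f, np.nan),
        "success": success,
        "is_outlier": False,
    })
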