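import numpy as np
import pandas as pd
import pytest

from haekit.config import AnalysisConfig, Config, KinematicsConfig, ThresholdGrid
from haekit.synthetic import MagnitudeModel, PositionSpec, SimulationConfig


@pytest.fixture(scope="session")
def kin() -> KinematicsConfig:
    return KinematicsConfig()


@pytest.fixture(scope="session")
def grid() -> ThresholdGrid:
    return ThresholdGrid()


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_sim() -> SimulationConfig:
    """Generator config with sensor noise switched off."""
    return SimulationConfig(noise_sd_a=(0.0, 0.0, 0.0), noise_sd_w=(0.0, 0.0, 0.0))


def small_sim(seed: int = 0, **kwargs) -> SimulationConfig:
    """A reduced season for fast statistical tests."""
    defaults = dict(n_teams=4, n_rounds=6, participation_prob=0.8, seed=seed)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def single_position_sim(seed: int = 0, rate_per_min: float | None = None,
                        **kwargs) -> SimulationConfig:
    """One position, degenerate 80-minute playing time: iid Poisson counts."""
    spec = PositionSpec("prop", "forward", 80.0, 80.0, 80.0,
                        carries_per_match=6.0, tackles_per_match=8.0,
                        rate_per_min=rate_per_min)
    defaults = dict(n_teams=4, n_rounds=8, participation_prob=1.0,
                    position_table=(spec,), player_sd=0.0, fixture_sd=0.0,
                    sequential_fraction=0.0, wear_miss_prob=0.0, seed=seed)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture()
def toy_involvements() -> pd.DataFrame:
    """Hand-built involvement table covering both roles and all sequences."""
    rows = [
        ("I0", "E0", "P1", "F1", 100.0, "ball-carrier", "one-on-one"),
        ("I1", "E0", "P2", "F1", 100.0, "tackler", "one-on-one"),
        ("I2", "E1", "P1", "F1", 200.0, "ball-carrier", "simultaneous"),
        ("I3", "E1", "P2", "F1", 200.0, "tackler", "simultaneous"),
        ("I4", "E1", "P3", "F1", 200.0, "tackler", "sequential"),
        ("I5", "E2", "P3", "F1", 300.0, "ball-carrier", "sequential"),
    ]
    return pd.DataFrame(rows, columns=[
        "involvement_id", "tackle_event_id", "player_id", "fixture_id",
        "timestamp", "role", "tackle_sequence"])
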