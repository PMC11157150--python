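import numpy as np
import pandas as pd
import pytest

from heatacc import budget as bud
from heatacc import preprocess, synthetic
from heatacc import thermal as th
from heatacc.io import AccBurst
from heatacc.preprocess import CenteredBurst


def random_burst(rng: np.random.Generator, n: int = 110, fs: float = 33.3) -> AccBurst:
    return AccBurst(
        individual_id="rnd",
        timestamp=pd.Timestamp("2020-10-01T12:00:00Z"),
        fs=fs,
        x_raw=rng.integers(0, 4096, n),
        y_raw=rng.integers(0, 4096, n),
        z_raw=rng.integers(0, 4096, n),
    )


def centered_from_arrays(x, y, z, fs: float = 33.3) -> CenteredBurst:
    return CenteredBurst(
        individual_id="c",
        timestamp=pd.Timestamp("2020-10-01T12:00:00Z"),
        fs=fs,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        z=np.asarray(z, dtype=float),
    )


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The full deterministic fixture suite, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return synthetic.make_fixture_suite(out, seed=0)


@pytest.fixture(scope="session")
def small_training_set():
    """250 labelled bursts across 5 well-separated behaviours (session-cached)."""
    return synthetic.make_training_set(
        n_per_behaviour=50,
        behaviours=("grazing", "browsing", "walking", "ruminating", "low-activity"),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_feature_matrix(small_training_set):
    from heatacc import features

    centered = [preprocess.center(lb.burst) for lb in small_training_set]
    labels = [lb.behaviour for lb in small_training_set]
    return features.feature_matrix(centered), labels


def scenario_cells(seed: int, null: bool = False, n_individuals: int = 3, n_days: int = 30,
                   **cfg_kwargs):
    """Simulate a deployment and aggregate afternoon budget cells."""
    cfg = synthetic.ScenarioConfig(
        seed=seed, n_individuals=n_individuals, n_days=n_days, **cfg_kwargs
    )
    if null:
        cfg.temp_slopes = {c: 0.0 for c in cfg.temp_slopes}
    timeline, weather, truth = synthetic.simulate_timeline(cfg)
    thermal = th.add_blackglobe(weather)
    records = bud.join_weather(timeline, thermal)
    records = bud.add_local_time(records, cfg.utc_offset_hours)
    cells = bud.time_budget(bud.afternoon_filter(records))
    return cells, records, thermal, cfg, truth


def diel_cells(seed: int, effect=None, factor: float = 0.5, n_days: int = 24):
    """Simulate a deployment with zeroed temperature slopes and build diel cells."""
    cfg = synthetic.ScenarioConfig(
        seed=seed,
        n_individuals=3,
        n_days=n_days,
        hot_day_effect=effect,
        hot_day_factor=factor,
    )
    cfg.temp_slopes = {c: 0.0 for c in cfg.temp_slopes}
    timeline, weather, _ = synthetic.simulate_timeline(cfg)
    thermal = th.add_blackglobe(weather)
    records = bud.add_local_time(
        bud.join_weather(timeline, thermal), cfg.utc_offset_hours
    )
    dmax = th.daily_max(bud.add_local_time(thermal, cfg.utc_offset_hours))
    extreme = th.select_extreme_days(dmax, n=10)
    return bud.diel_budget(records, extreme)
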