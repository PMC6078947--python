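"""Shared fixtures: reduced-scale synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from compdrop import SimulationConfig, simulate_session1, simulate_session2
from compdrop.containers import DropTable


def small_config(**overrides) -> SimulationConfig:
    """Reduced-scale study: fewer subjects/channels/items, shorter epochs."""
    params = dict(
        n_subjects=4,
        n_channels=12,
        sampling_rate=128.0,
        epoch_span=(-100.0, 700.0),
        n_categories=5,
        n_exemplars_per_category=4,
        n_items_s2=24,
        signal_window=(80.0, 400.0),
        effect_size=1.5,
        seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def s1_data(config):
    return simulate_session1(config)


@pytest.fixture(scope="session")
def s2_data(config):
    return simulate_session2(config)


def make_drop_table(
    n_items=120,
    grid_shape=(6, 9),
    effect=0.0,
    n_subjects=6,
    seed=0,
    effect_squares=None,
):
    """Synthetic DropTable with an optional planted remembered-vs-forgotten
    shift on selected grid squares, bypassing the EEG stages."""
    rng = np.random.default_rng(seed)
    n_train, n_test = grid_shape
    drops = rng.normal(0.0, 1.0, size=(n_items, n_train, n_test))
    y = rng.permutation(np.arange(n_items) % 2)
    if effect:
        if effect_squares is None:
            effect_squares = np.s_[: n_train // 2, : n_test // 2]
        block = drops[y == 1]
        block[(np.s_[:],) + (effect_squares if isinstance(effect_squares, tuple) else (effect_squares,))] += effect
        drops[y == 1] = block
    items = pd.DataFrame(
        {
            "subject": np.arange(n_items) % n_subjects,
            "item": np.arange(n_items),
            "configuration": "0011",
            "first_correct_round": 3,
            "recalled_s3": y,
            "rt_drop": rng.normal(0, 0.5, n_items),
        }
    )
    return DropTable(
        drops=drops,
        items=items,
        train_times=np.arange(n_train) * 20.0 + 80.0,
        test_times=np.arange(n_test) * 20.0,
    )
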