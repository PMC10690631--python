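import numpy as np
import pytest

import gravicept as gc

# Printed kinematic table: duration -> {label: (v0, vt)} in m/s.
TABLE1 = {
    1.1: {"plus_g": (2.7, 13.5), "minus_g": (13.5, 2.7), "zero_g": (8.1, 8.1)},
    1.0: {"plus_g": (4.0, 13.8), "minus_g": (13.8, 4.0), "zero_g": (8.9, 8.9)},
    0.9: {"plus_g": (5.5, 14.3), "minus_g": (14.3, 5.5), "zero_g": (9.9, 9.9)},
    0.8: {"plus_g": (7.3, 15.1), "minus_g": (15.1, 7.3), "zero_g": (11.2, 11.2)},
}

# Printed predictor table (ms): gravity predictors at engagement times
# 0..600 ms every 100 ms, plus the known-size optical column.
TABLE2 = {
    ("minus_g", 1.1): ([551, 608, 665, 721, 777, 832, 887], 1063),
    ("minus_g", 1.0): ([541, 597, 651, 705, 758, 810, 859], 971),
    ("minus_g", 0.9): ([528, 580, 632, 682, 731, 777, 820], 879),
    ("minus_g", 0.8): ([508, 557, 605, 650, 692, 731, 765], 784),
    ("zero_g", 1.1): ([755, 802, 846, 889, 929, 967, 1001], 1100),
    ("zero_g", 1.0): ([717, 760, 800, 839, 875, 907, 936], 1000),
    ("zero_g", 0.9): ([674, 713, 749, 783, 814, 841, 864], 900),
    ("zero_g", 0.8): ([627, 661, 693, 721, 746, 768, 784], 801),
    ("plus_g", 1.1): ([1100] * 7, 1112),
    ("plus_g", 1.0): ([1000] * 7, 1012),
    ("plus_g", 0.9): ([900] * 7, 911),
    ("plus_g", 0.8): ([800] * 7, 811),
}


@pytest.fixture(scope="session")
def geometry():
    return gc.SceneGeometry()


@pytest.fixture(scope="session")
def conditions(geometry):
    return gc.build_condition_table(geometry)


@pytest.fixture(scope="session")
def predictor_table(geometry, conditions):
    return gc.build_predictor_table(geometry, conditions=conditions)


@pytest.fixture(scope="session")
def default_summaries(predictor_table):
    """Aggregated synthetic dataset at the default generative parameters."""
    params = gc.GenerativeParams(seed=11)
    trials = gc.filter_outliers(gc.simulate_trials(params, predictor_table))
    return gc.aggregate(trials)


@pytest.fixture(scope="session")
def fast_sampler():
    """Reduced sampler settings for unit tests (seconds, not minutes)."""
    return gc.SamplerConfig(n_walkers=64, n_steps=700, n_burn=300, seed=7)


@pytest.fixture(scope="session")
def default_fit(default_summaries, predictor_table):
    """One full-settings fit of the engagement-450 model, shared by tests."""
    return gc.fit_mixed(
        default_summaries,
        predictor_table,
        ("g_450",),
        settings=gc.SamplerConfig(seed=2),
    )
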