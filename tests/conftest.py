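"""Shared fixtures: a small synthetic corpus and cheaply trained models.

Unit tests use a deliberately small corpus (12 days) and small networks
(16 units, few epochs) so the suite stays fast; the acceptance tests
train at the full study scale themselves.
"""

import numpy as np
import pandas as pd
import pytest

import glucodss as gd


@pytest.fixture(scope="session")
def small_corpus():
    cfg = gd.CorpusConfig(train_days=10, test_days=2)
    return gd.make_training_corpus(cfg, seed=42)


@pytest.fixture(scope="session")
def small_config():
    return gd.ModelConfig(variant="p", ph=30, hidden=16, epochs=8,
                          patience=4, seed=3)


@pytest.fixture(scope="session")
def trained_p(small_corpus, small_config):
    return gd.train(small_corpus.split.train, small_config)


@pytest.fixture(scope="session")
def trained_np(small_corpus, small_config):
    import dataclasses
    cfg = dataclasses.replace(small_config, variant="np")
    return gd.train(small_corpus.split.train, cfg)


@pytest.fixture()
def simple_series():
    """2-day gap-free series at constant basal with one meal+bolus."""
    sc = gd.Scenario(duration=2880, basal=1 / 60,
                     meals=[(600.0, 60.0, True)], boluses=[(600.0, 6.0)],
                     cgm_noise_sd=0.0)
    return gd.simulate(gd.MinimalModelParams(), sc).series


def make_series(cgm, insulin=None, cho=None, step=5,
                start="2024-01-01") -> gd.GlucoseTimeSeries:
    """Build a series from plain arrays (NaN in cgm marks missing)."""
    cgm = np.asarray(cgm, dtype=float)
    n = len(cgm)
    grid = gd.TimeGrid(pd.Timestamp(start), step, n)
    insulin = np.zeros(n) if insulin is None else np.asarray(insulin, float)
    cho = np.zeros(n) if cho is None else np.asarray(cho, float)
    return gd.GlucoseTimeSeries(grid, cgm, insulin, cho, np.isnan(cgm))
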