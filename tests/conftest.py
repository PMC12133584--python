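import numpy as np
import pytest

from cpmkit import synthetic


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-signal dataset (24 subjects, 20 parcels, 4 networks)."""
    cfg = synthetic.preset("tiny", seed=7)
    conn, behavior, truth = synthetic.generate(cfg)
    return cfg, conn, behavior, truth


@pytest.fixture(scope="session")
def toy_edges():
    """6 subjects × 6 edges (4 parcels) with a hand-checkable outcome."""
    rng = np.random.default_rng(12345)
    X = rng.normal(size=(6, 6))
    y = np.array([3.0, -1.0, 0.5, 2.0, -2.5, 1.0])
    return X, y


@pytest.fixture(scope="session")
def discordant_dataset():
    """The calibrated misprediction scenario (30% sign-inverted subjects)."""
    cfg = synthetic.preset("discordant", seed=11)
    conn, behavior, truth = synthetic.generate(cfg)
    return cfg, conn, behavior, truth
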