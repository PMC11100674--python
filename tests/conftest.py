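import warnings

import numpy as np
import pytest

import sarcvae as sv
from sarcvae.params import LatticeConfig, ModelConfig

warnings.filterwarnings("ignore", message="reducible rate matrix")


@pytest.fixture()
def reduced_config() -> ModelConfig:
    """The small calibration lattice (full kinetics, 54 heads)."""
    return sv.reduced_lattice_config()


@pytest.fixture()
def tiny_config() -> ModelConfig:
    """A minimal lattice + short run for fast smoke tests."""
    cfg = sv.reduced_lattice_config(lattice=dict(
        nodes_per_thick=6, nodes_per_thin=3, heads_per_node=1,
        half_sarcomere_length=160.0))
    cfg.duration = 200.0
    return cfg


@pytest.fixture()
def corpus_config() -> ModelConfig:
    """Single-head-per-crown lattice used for training corpora."""
    return sv.reduced_lattice_config(lattice=dict(heads_per_node=1))


def make_rng(*seed):
    return np.random.default_rng(np.random.SeedSequence(seed))
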