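"""Shared fixtures: small synthetic corpora and scoring backends."""

import numpy as np
import pytest

from viratax.alignment import AlignerParams, InternalAligner
from viratax.simulate import SimulationConfig, simulate_corpus


@pytest.fixture(scope="session")
def aligner():
    return InternalAligner(AlignerParams())


@pytest.fixture(scope="session")
def small_corpus():
    """2 families x 6 genomes with short genes — cheap enough for repeated
    alignment-backed tests."""
    cfg = SimulationConfig(
        n_families=2,
        genomes_per_family=6,
        genes_per_ancestor=(2, 3),
        gene_length=(40, 60),
        seed=11,
    )
    return simulate_corpus(cfg)


@pytest.fixture(scope="session")
def default_corpus():
    """The canonical study conditions: 3 families x 10 genomes."""
    return simulate_corpus(SimulationConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
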