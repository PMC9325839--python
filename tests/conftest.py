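"""Shared fixtures: a small synthetic universe and a lightly trained model.

Everything is generated programmatically at session start; no data files.
"""

from __future__ import annotations

import pytest

from promgen.model import SmilesRnnGenerator
from promgen.universe import UniverseConfig, build_universe


@pytest.fixture(scope="session")
def small_universe():
    """50/200/500 universe used by curation-recovery and chemistry tests."""
    return build_universe(UniverseConfig(n_multi=50, n_single=200, n_none=500, seed=7))


@pytest.fixture(scope="session")
def universe_smiles(small_universe):
    return [c.smiles for c in small_universe.compounds]


@pytest.fixture(scope="session")
def trained_generator(universe_smiles):
    """A small pretrained model for sampling/NLL behaviour tests.

    Deliberately under-trained (8 epochs, hidden 64): enough to emit mostly
    well-formed strings, cheap enough for the suite.
    """
    gen = SmilesRnnGenerator(
        hidden_size=64, embedding_dim=32, n_epochs=8, random_state=11
    )
    return gen.fit(universe_smiles)
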