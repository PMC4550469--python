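import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from apiflora.simulate import SimConfig, simulate_reference, simulate_scenario


@pytest.fixture(scope="session")
def taxonomy():
    """A small deterministic reference taxonomy (5 fam x 2 gen x 2 sp)."""
    return simulate_reference(seed=42)


@pytest.fixture(scope="session")
def tiny_scenario():
    """A cheap complete scenario: 3 honeys + replicate, 400 reads each."""
    return simulate_scenario(seed=7, n_samples=3, n_reads=400, n_grains=300)


@pytest.fixture()
def error_free_config():
    return SimConfig(
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        truncation_rate=0.0,
        tagless_contaminant_fraction=0.0,
    )
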