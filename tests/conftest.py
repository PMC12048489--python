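import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import fecomap as fm

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_world():
    """A mid-size synthetic connectome shared across tests."""
    neurons, synapses, gt = fm.generate_connectome(fm.SyntheticSpec.small(), 3)
    return neurons, synapses, gt, fm.build_edge_list(synapses, neurons)


@pytest.fixture(scope="session")
def paper_world():
    """A reconstruction-scale synthetic connectome (80 + 14 seeds)."""
    neurons, synapses, gt = fm.generate_connectome(fm.SyntheticSpec.paper_scale(), 1)
    return neurons, synapses, gt, fm.build_edge_list(synapses, neurons)


@pytest.fixture(scope="session")
def tiny_fixture_dir():
    """The shipped hand-checkable tiny fixture."""
    return DATA_DIR / "tiny"
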