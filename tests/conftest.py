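import pytest

from ikslab.ephys_analysis import VoltageProtocol
from ikslab.synthetic_data import generate_cell_population


@pytest.fixture(scope="session")
def protocol():
    return VoltageProtocol()


@pytest.fixture(scope="session")
def small_populations(protocol):
    """Five synthetic cells per expression group, default noise."""
    return {
        grp: generate_cell_population(grp, 5, seed=42, protocol=protocol)
        for grp in ("WT", "HOM", "HET")
    }


@pytest.fixture(scope="session")
def fast_gate_protocol():
    """Short protocol paired with fast-relaxing gates: keeps exhaustive
    oracle comparisons cheap while step >> tau still holds."""
    return VoltageProtocol(step_ms=2000.0, tail_ms=1000.0, pre_ms=50.0)
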