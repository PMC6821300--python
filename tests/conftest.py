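import math

import pytest

from retinet.simulate import SimulationConfig


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    """Small but non-trivial study conditions shared across tests."""
    return SimulationConfig(
        n_loci=200,
        sites_per_locus=300,
        gamma=0.1,
        t_internal=math.log(2.0),
        seed=42,
    )


@pytest.fixture()
def toy_alignment() -> dict[str, str]:
    """Eight-taxon toy with known column classes.

    Columns: 0 monomorphic, 1 biallelic A/G, 2 triallelic, 3 gapped,
    4 biallelic C/T.
    """
    return {
        "p1": "AACAC",
        "p2": "AGC-T",
        "p3": "AGTAT",
        "p4": "AAGAC",
        "p5": "AACAC",
        "p6": "AACAC",
        "p7": "AACAC",
        "out": "AACAC",
    }
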