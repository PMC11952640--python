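import numpy as np
import pytest

from multigwas.popsim import LDBlockSpec, simulate_frequencies, simulate_panel


@pytest.fixture(scope="session")
def three_group_table():
    """2,000 variants, three diverged groups, moderate F_ST."""
    return simulate_frequencies(
        2_000,
        ["AFR", "EUR", "EAS"],
        {"AFR": 0.15, "EUR": 0.08, "EAS": 0.12},
        seed=101,
    )


@pytest.fixture(scope="session")
def three_group_panel(three_group_table):
    """900 samples (300 per group) with block LD."""
    return simulate_panel(
        three_group_table,
        {"AFR": 300, "EUR": 300, "EAS": 300},
        LDBlockSpec(block_length_bp=100_000, rho=0.8),
        seed=102,
    )


@pytest.fixture(scope="session")
def independent_panel():
    """Two groups, no LD (rho=0): dosages are independent binomials."""
    vt = simulate_frequencies(
        1_000, ["AFR", "EUR"], {"AFR": 0.15, "EUR": 0.08}, seed=103
    )
    return simulate_panel(vt, {"AFR": 500, "EUR": 500}, LDBlockSpec(rho=0.0), seed=104)
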