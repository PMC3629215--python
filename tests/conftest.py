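import numpy as np
import pytest

from neodemic.io import HaplogroupCounts


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20130417)


@pytest.fixture()
def small_counts():
    return HaplogroupCounts(
        populations=["P1", "P2", "H"],
        haplogroups=["a", "b", "c", "d"],
        counts=np.array([[10, 5, 3, 2], [1, 2, 8, 9], [3, 3, 7, 7]]),
    )


@pytest.fixture(scope="session")
def sdg_reference_table():
    """Small shared TP/S/SDG reference table (session-scoped: ~30 s)."""
    from neodemic.modelchoice import simulate_reference_table

    return simulate_reference_table(3000, seed=20130417)
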