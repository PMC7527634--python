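import numpy as np
import pytest

import recspot as rs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_sequences():
    """200 random DNA records of varied length for property checks."""
    gen = np.random.default_rng(77)
    out = []
    for i in range(200):
        L = int(gen.integers(10, 120))
        out.append(rs.DnaSequence(f"r{i}", "".join("ACGT"[j] for j in gen.integers(0, 4, L))))
    return out


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """A small planted-signal dataset shared by selection/model/evaluation tests."""
    spec = rs.SimulationSpec(
        n_pos=40, n_neg=40, length_low=200, length_high=300, effect=0.2, seed=5
    )
    return rs.generate_synthetic_dataset(spec)
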