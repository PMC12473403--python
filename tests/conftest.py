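import numpy as np
import pandas as pd
import pytest

from commstab import AbundanceTable, SampleMeta


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """Six samples x three species over two levels, hand-checkable."""
    data = pd.DataFrame(
        {
            "spA": [2.0, 4.0, 6.0, 5.0, 5.0, 5.0],
            "spB": [1.0, 3.0, 2.0, 0.0, 4.0, 2.0],
            "spC": [0.0, 0.0, 0.0, 3.0, 3.0, 3.0],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    return AbundanceTable(data)


@pytest.fixture
def tiny_meta() -> SampleMeta:
    meta = pd.DataFrame(
        {
            "level": ["ND", "ND", "ND", "ED", "ED", "ED"],
            "plot": ["p1"] * 3 + ["p2"] * 3,
            "point": [f"q{i}" for i in range(1, 4)] * 2,
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SampleMeta(meta, levels=("ND", "LD", "MD", "HD", "ED"))


def random_table(rng: np.random.Generator, n_samples: int, n_species: int) -> AbundanceTable:
    """Random strictly-positive-total abundance matrix for oracle tests."""
    counts = rng.integers(0, 20, size=(n_samples, n_species)).astype(float)
    counts[:, 0] += 1  # avoid empty samples and all-zero first species
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"sp{j}" for j in range(n_species)],
        )
    )
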