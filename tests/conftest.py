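import numpy as np
import pytest

from enhkit import DnaSequence, PropertyTable, generate_synthetic_dataset
from enhkit.property_index import example_shift_slide_table


@pytest.fixture(scope="session")
def shift_slide_table() -> PropertyTable:
    """The bundled Shift/Slide fixture table (worked-example values)."""
    return example_shift_slide_table()


@pytest.fixture(scope="session")
def worked_sequence() -> DnaSequence:
    """The 8-bp worked-example sequence."""
    return DnaSequence("example", "TACATTCA")


@pytest.fixture
def random_table():
    """Factory for seeded random property tables of any size."""

    def make(n_properties: int, seed: int = 0) -> PropertyTable:
        rng = np.random.default_rng(seed)
        names = tuple(f"prop{i:03d}" for i in range(n_properties))
        return PropertyTable(names, rng.normal(size=(n_properties, 16)))

    return make


@pytest.fixture
def random_sequence():
    """Factory for seeded random DNA sequences."""

    def make(length: int, seed: int = 0, ident: str = "rand") -> DnaSequence:
        rng = np.random.default_rng(seed)
        return DnaSequence(ident, "".join(rng.choice(list("ACGT"), size=length)))

    return make


@pytest.fixture(scope="session")
def benchmark_shaped_dataset():
    """A 400-sequence, 200-bp, 2:1:1 synthetic dataset (default biases)."""
    return generate_synthetic_dataset(400, 200, (2, 1, 1), seed=11)
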