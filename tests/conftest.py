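import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from autoppi import DescriptorConfig, ProteinRecord

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def two_scale_table() -> pd.DataFrame:
    """A tiny 2 x 20 property table with known, non-degenerate values."""
    rng = np.random.default_rng(42)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    return pd.DataFrame(
        rng.normal(size=(2, 20)),
        index=["scale_a", "scale_b"],
        columns=letters,
    )


@pytest.fixture
def small_config(two_scale_table) -> DescriptorConfig:
    """lag=3 with two scales: k = 343 + 6 = 349."""
    return DescriptorConfig(lag=3, property_table=two_scale_table)


@pytest.fixture
def tiny_proteins() -> list[ProteinRecord]:
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return [
        ProteinRecord(f"p{i}", "".join(rng.choice(letters, size=rng.integers(20, 40))))
        for i in range(6)
    ]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(letters, size=length))
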