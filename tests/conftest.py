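import numpy as np
import pytest

from propseq.tables import AA_LETTERS, PropertyTable


def toy_property_table(name="toy", **overrides):
    """A full 20-residue table: injective defaults (1..20) plus overrides."""
    values = {a: float(i + 1) for i, a in enumerate(AA_LETTERS)}
    values.update({k: float(v) for k, v in overrides.items()})
    return PropertyTable(name, values)


@pytest.fixture
def toy_table():
    return toy_property_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_factor_matrix(rng, m=6):
    return rng.standard_normal((m, 5))
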