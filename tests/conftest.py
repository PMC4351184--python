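import numpy as np
import pytest

from spliceaudit import DnaSeq, assemble
from spliceaudit.fixtures import (
    ModelConstructParams,
    make_model_construct,
    make_repaired_construct,
)


@pytest.fixture(scope="session")
def model_construct():
    """Default-geometry model construct (junction + linker donors planted)."""
    return make_model_construct(ModelConstructParams(seed=1))


@pytest.fixture(scope="session")
def repaired_construct():
    """Wobble-repaired construct (junction donor destroyed, linker donor kept)."""
    return make_repaired_construct(ModelConstructParams(seed=1))


@pytest.fixture(scope="session")
def model_assembled(model_construct):
    return assemble(model_construct)


def random_dna(rng: np.random.Generator, n: int) -> DnaSeq:
    return DnaSeq("".join("ACGT"[i] for i in rng.integers(0, 4, size=n)))
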