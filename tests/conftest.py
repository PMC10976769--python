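import random

import numpy as np
import pytest

from mirfam.records import MirSeqRecord
from mirfam.synthdata import CANONICAL_MIR166_3P, SimSpec


@pytest.fixture
def rng():
    return random.Random(20240501)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def sim_spec():
    return SimSpec(seed=11)


@pytest.fixture
def canonical_mature():
    return MirSeqRecord(id="miR166-3p", sequence=CANONICAL_MIR166_3P)


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))
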