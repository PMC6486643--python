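import random

import pytest

from stripalign import ReferencePack, build_index


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def worked_example():
    """The AATGG query / AATCTGG reference pair with its index."""
    pack = ReferencePack([("ref", "AATCTGG")])
    return pack, build_index(pack), "AATGG"


@pytest.fixture()
def rng():
    return random.Random(20240917)
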