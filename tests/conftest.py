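import random

import pytest

from acepamir import datasets


@pytest.fixture(scope="session")
def reported():
    """The 14 bundled onion miRNAs with published statistics."""
    return datasets.load_reported_mirnas()


@pytest.fixture(scope="session")
def reported_by_name(reported):
    return {m.name: m for m in reported}


@pytest.fixture()
def rng():
    return random.Random(20240901)


def random_rna(rng, n):
    return "".join(rng.choice("AUGC") for _ in range(n))
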