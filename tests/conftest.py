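import numpy as np
import pytest

from bgcmine import data as bundled
from bgcmine.records import Gene


@pytest.fixture(scope="session")
def toy_profiles():
    return bundled.toy_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, start, end, strand=1, translation="M",
              record_id="rec"):
    return Gene(gene_id=gene_id, record_id=record_id,
                parts=[(start, end)], strand=strand, translation=translation)


@pytest.fixture()
def gene_factory():
    return make_gene
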