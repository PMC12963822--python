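import numpy as np
import pytest

from gatmerip import (
    EdgeListRecord,
    SyntheticSpec,
    build_network,
    generate,
    make_toy_quantification,
)


def net_from_pairs(pairs, source="fix"):
    """Build a network straight from (a, b) gene-symbol pairs."""
    return build_network([EdgeListRecord(a, b, source) for a, b in pairs])


@pytest.fixture(scope="session")
def small_synth():
    """A 200-gene, 2-dataset synthetic instance shared across tests."""
    return generate(SyntheticSpec(n_genes=200, n_datasets=2, seed=11))


@pytest.fixture(scope="session")
def toy_quant(tmp_path_factory):
    """Toy peak + expression tables exercising every filter branch."""
    outdir = tmp_path_factory.mktemp("toyquant")
    return make_toy_quantification(20, outdir, seed=3)


@pytest.fixture()
def path_net():
    """Path graph A - B - C."""
    return net_from_pairs([("A", "B"), ("B", "C")])


@pytest.fixture()
def triangle_net():
    return net_from_pairs([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
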