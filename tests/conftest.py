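import numpy as np
import pytest

from foldbroker import FoldTree, Edge, build_ideal_polypeptide
from foldbroker.fixtures import (
    make_vignette1_fixture,
    make_vignette2_fixture,
    make_vignette3_fixture,
)


@pytest.fixture
def helix10():
    return build_ideal_polypeptide(10, torsion_preset="helix")


@pytest.fixture
def jump_tree_10():
    """Ten residues, jump 3->8, cut at 5, backward fold 8->6."""
    return FoldTree(
        (
            Edge(1, 3, "PEPTIDE"),
            Edge(3, 5, "PEPTIDE"),
            Edge(3, 8, 1),
            Edge(8, 6, "PEPTIDE"),
            Edge(8, 10, "PEPTIDE"),
        ),
        root=1,
        cuts=(5,),
    )


@pytest.fixture(scope="session")
def vignette1():
    return make_vignette1_fixture(7)


@pytest.fixture(scope="session")
def vignette2():
    return make_vignette2_fixture(7)


@pytest.fixture(scope="session")
def vignette3():
    return make_vignette3_fixture(7)


def random_conformation(rng, n=None, preset_noise=40.0):
    """Random single-chain conformation with torsions drawn around broad
    backbone values; used by round-trip and locality property tests."""
    n = n or int(rng.integers(8, 30))
    triples = [
        (
            float(rng.uniform(-180, 180)),
            float(rng.uniform(-180, 180)),
            float(180.0 + rng.uniform(-10, 10)),
        )
        for _ in range(n)
    ]
    return build_ideal_polypeptide(n, torsion_preset=triples)
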