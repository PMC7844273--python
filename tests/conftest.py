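import pytest

from mitorearr import canonical_vertebrate_order, extract_order
from mitorearr.data import load_reference_annotation


@pytest.fixture(scope="session")
def eel_annotation():
    """The published rearranged eel mitogenome annotation (17,673 bp, 40 features)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def eel_order(eel_annotation):
    return extract_order(eel_annotation)


@pytest.fixture(scope="session")
def canonical():
    return canonical_vertebrate_order()


#: 15-tip family tree in which the five rearranged-mitogenome eel families
#: form one clade at the bottom, mirroring the published phylogeny's shape.
FAMILY_TREE_NEWICK = (
    "(Outgroup,(Nemichthyidae,(Serrivomeridae,(Anguillidae,(Moringuidae,"
    "(Chlopsidae,(Muraenidae,(Myrocongridae,(Heterenchelyidae,"
    "(Synaphobranchidae,((Derichthyidae,Nettastomatidae),"
    "(Congridae,(Muraenesocidae,Ophichthidae)))))))))))));"
)

REARRANGED_FAMILIES = (
    "Derichthyidae", "Nettastomatidae", "Congridae",
    "Muraenesocidae", "Ophichthidae",
)


@pytest.fixture(scope="session")
def family_tree():
    states = {}
    for tip in (
        "Outgroup", "Nemichthyidae", "Serrivomeridae", "Anguillidae",
        "Moringuidae", "Chlopsidae", "Muraenidae", "Myrocongridae",
        "Heterenchelyidae", "Synaphobranchidae",
    ):
        states[tip] = "canonical"
    for tip in REARRANGED_FAMILIES:
        states[tip] = "rearranged"
    return FAMILY_TREE_NEWICK, states
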