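from __future__ import annotations

import textwrap

import dendropy
import pytest

from alienphylo import patristic_matrix


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


@pytest.fixture(scope="session")
def four_tip_tree():
    """Balanced quartet, all branch lengths 1."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def four_tip_dm(four_tip_tree):
    return patristic_matrix(four_tip_tree)


@pytest.fixture(scope="session")
def five_tip_tree():
    """Asymmetric 5-tip tree: (A,B) deep split vs the ((C,D),E) clade."""
    return tree_from_newick("((A:1,B:1):3,((C:1,D:1):1,E:2):2);")


@pytest.fixture(scope="session")
def five_tip_dm(five_tip_tree):
    return patristic_matrix(five_tip_tree)


WELL_FORMED_CSV = textwrap.dedent(
    """\
    species,family,genus,lifeform,origin,pathway,status
    Eichhornia crassipes,Pontederiaceae,Eichhornia,perennial,america,ornamental,invasive
    Ambrosia artemisiifolia,Asteraceae,Ambrosia,annual,america,unintentional,invasive
    Tagetes erecta,Asteraceae,Tagetes,annual,america,ornamental,naturalized
    Trifolium repens,Fabaceae,Trifolium,perennial,europe;temperate asia,forage,naturalized
    Avena sativa,Poaceae,Avena,annual,europe,food,casual
    Digitalis purpurea,Plantaginaceae,Digitalis,biennial,europe,medicinal,casual
    """
)


@pytest.fixture()
def checklist_csv(tmp_path):
    path = tmp_path / "checklist.csv"
    path.write_text(WELL_FORMED_CSV)
    return path
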