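import numpy as np
import pytest

from famtrace.simulate import FamilySimConfig, simulate_survey_dataset
from famtrace.trees import SpeciesTree, random_species_tree

# A hand-built miniature eukaryote phylogeny with labelled supergroups,
# used for origin-labelling and lineage-aggregation tests.
EUK_NEWICK = (
    "((((((Hsap:0.2,Mmus:0.2):0.1,(Xtro:0.25,Drer:0.25):0.05)Metazoa:0.2,"
    "(Scer:0.4,Amac:0.4)Fungi:0.1)Opisthokonta:0.2,"
    "(Ddis:0.6,Ehis:0.6)Amoebozoa:0.1):0.1,"
    "(((Atha:0.3,Crei:0.3)Viridiplantae:0.2,Cmer:0.5)Archaeplastida:0.2,"
    "Cpar:0.7):0.1):0.1,"
    "(((Tpse:0.4,Esil:0.4)Stramenopiles:0.2,(Tthe:0.45,Pfal:0.45)Alveolata:0.15)SAR:0.2,"
    "Tvag:0.8):0.1);"
)

EUK_TAXONOMY = {
    "Hsap": "Metazoa",
    "Mmus": "Metazoa",
    "Xtro": "Metazoa",
    "Drer": "Metazoa",
    "Scer": "Fungi",
    "Amac": "Fungi",
    "Ddis": "Amoebozoa",
    "Ehis": "Amoebozoa",
    "Atha": "Viridiplantae",
    "Crei": "Viridiplantae",
    "Cmer": "Rhodophyta",
    "Cpar": "Glaucophyta",
    "Tpse": "Stramenopiles",
    "Esil": "Stramenopiles",
    "Tthe": "Alveolata",
    "Pfal": "Alveolata",
    "Tvag": "Metamonada",
}


@pytest.fixture(scope="session")
def euk_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(EUK_NEWICK, EUK_TAXONOMY)


@pytest.fixture(scope="session")
def small_tree() -> SpeciesTree:
    return random_species_tree(8, seed=7, mean_root_to_tip=0.5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 species x 4 families x 100 decoys: fast end-to-end input."""
    tree = random_species_tree(12, seed=5, mean_root_to_tip=0.6)
    cfg = FamilySimConfig(
        dup_rate=0.2, loss_rate=0.2, background_size=100, seed=5
    )
    return tree, simulate_survey_dataset(tree, 4, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
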