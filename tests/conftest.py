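import pytest

from darkpath.pathway_model import pathway_db_from_dict
from darkpath.synthetic_data import SyntheticConfig, make_toy_pathway_db


@pytest.fixture(scope="session")
def toy_db():
    """Hand-built three-protein database: one pathway, one sub-pathway,
    one reaction (A + catalyst B -> complex of C) — small enough that every
    derived quantity can be checked by hand."""
    return pathway_db_from_dict(
        {
            "schema_version": 1,
            "genes": [
                {"symbol": "A", "tdl": "Tbio"},
                {"symbol": "B", "tdl": "Tdark"},
                {"symbol": "C", "tdl": "Tbio"},
            ],
            "entities": [
                {"id": "eA", "kind": "protein", "gene": "A"},
                {"id": "eB", "kind": "protein", "gene": "B"},
                {"id": "eC", "kind": "protein", "gene": "C"},
                {"id": "cx", "kind": "complex", "components": ["eC"]},
            ],
            "reactions": [
                {
                    "id": "r1",
                    "inputs": ["eA"],
                    "outputs": ["cx"],
                    "catalysts": ["eB"],
                    "summation": "A is converted by B into a C-containing complex",
                }
            ],
            "pathways": [
                {"id": "sub", "name": "sub-process", "children": ["r1"],
                 "summation": "the catalytic core"},
                {"id": "top", "name": "toy pathway", "children": ["sub"],
                 "summation": "a toy signaling pathway"},
            ],
            "top_level": ["top"],
        }
    )


@pytest.fixture(scope="session")
def synth_cfg():
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def synth_db(synth_cfg):
    return make_toy_pathway_db(synth_cfg)
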