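import numpy as np
import pandas as pd
import pytest

from chimeracomplex.annotation import compendium_from_mapping


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_annot():
    """Six proteins spread over chromosomes 1-3 and 16."""
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(1, 7)],
        "protein_id": [f"P{i}" for i in range(1, 7)],
        "chromosome": [1, 2, 3, 3, 16, 16],
    })


@pytest.fixture
def toy_compendium():
    """C1 spans chr1+chr2, C2 sits entirely on chr3."""
    return compendium_from_mapping({"C1": {"P1", "P2"}, "C2": {"P3", "P4"}})


def random_annotation(rng, n=40):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "protein_id": [f"P{i}" for i in range(n)],
        "chromosome": rng.integers(1, 17, size=n),
    })


def random_compendium(rng, annot, n_complexes=8, max_size=5):
    proteins = list(annot["protein_id"])
    members = {}
    for i in range(n_complexes):
        size = int(rng.integers(2, max_size + 1))
        members[f"C{i}"] = set(rng.choice(proteins, size=size, replace=False))
    return compendium_from_mapping(members)
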