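import numpy as np
import pytest

from otterdiet.taxonomy import RANKS, TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def fish_tree() -> TaxonomyTree:
    """Hand-built lineage fixture with two fish clades and a mammal."""
    rows = [
        ("Animalia", "kingdom", None),
        ("Chordata", "phylum", "Animalia"),
        ("Actinopterygii", "class", "Chordata"),
        ("Salmoniformes", "order", "Actinopterygii"),
        ("Salmonidae", "family", "Salmoniformes"),
        ("Salmo", "genus", "Salmonidae"),
        ("Salmo_trutta", "species", "Salmo"),
        ("Salmo_salar", "species", "Salmo"),
        ("Cypriniformes", "order", "Actinopterygii"),
        ("Cyprinidae", "family", "Cypriniformes"),
        ("Rutilus", "genus", "Cyprinidae"),
        ("Rutilus_rutilus", "species", "Rutilus"),
        ("Scardinius", "genus", "Cyprinidae"),
        ("Scardinius_erythrophthalmus", "species", "Scardinius"),
        ("Mammalia", "class", "Chordata"),
        ("Lutra_lutra", "species", "Mammalia"),
    ]
    return TaxonomyTree(TaxonNode(i, i, r, p) for i, r, p in rows)


def random_tree(rng: np.random.Generator, n_nodes: int = 30) -> TaxonomyTree:
    """A random rank-consistent forest for oracle-based tests."""
    nodes = [TaxonNode("root", "root", "kingdom", None)]
    ranks_of = {"root": 0}
    for i in range(1, n_nodes):
        # pick any existing node whose rank allows a child
        while True:
            parent = nodes[rng.integers(len(nodes))]
            prank = ranks_of[parent.id]
            if prank < len(RANKS) - 1:
                break
        rank_idx = int(rng.integers(prank + 1, len(RANKS)))
        nid = f"t{i}"
        nodes.append(TaxonNode(nid, nid, RANKS[rank_idx], parent.id))
        ranks_of[nid] = rank_idx
    return TaxonomyTree(nodes)
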