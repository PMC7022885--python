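"""Shared fixtures: small hand-built taxonomies and random-tree factories."""

from __future__ import annotations

import numpy as np
import pytest

from rhizomine.taxonomy import NO_RANK, TaxonomyNode, TaxonomyTree


@pytest.fixture
def seven_node_tree() -> TaxonomyTree:
    """root -> 2 superkingdoms -> 2 phyla -> 2 families (depth 3)."""
    nodes = [
        TaxonomyNode(1, 1, NO_RANK, "root"),
        TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
        TaxonomyNode(3, 1, "superkingdom", "Eukaryota"),
        TaxonomyNode(4, 2, "phylum", "Actinobacteria"),
        TaxonomyNode(5, 3, "phylum", "Ascomycota"),
        TaxonomyNode(6, 4, "family", "Streptomycetaceae"),
        TaxonomyNode(7, 5, "family", "Nectriaceae"),
    ]
    return TaxonomyTree(nodes)


@pytest.fixture
def ranked_tree() -> TaxonomyTree:
    """Small tree with a full species -> genus -> family -> phylum chain
    and sibling species, for LCA and rank-aggregation tests."""
    nodes = [
        TaxonomyNode(1, 1, NO_RANK, "root"),
        TaxonomyNode(10, 1, "superkingdom", "Bacteria"),
        TaxonomyNode(20, 10, "phylum", "Proteobacteria"),
        TaxonomyNode(21, 10, "phylum", "Actinobacteria"),
        TaxonomyNode(30, 20, "family", "Burkholderiaceae"),
        TaxonomyNode(31, 21, "family", "Micrococcaceae"),
        TaxonomyNode(40, 30, "genus", "Burkholderia"),
        TaxonomyNode(50, 40, "species", "B. cepacia"),
        TaxonomyNode(51, 40, "species", "B. gladioli"),
        TaxonomyNode(41, 31, "genus", "Arthrobacter"),
        TaxonomyNode(52, 41, "species", "A. aurescens"),
    ]
    return TaxonomyTree(nodes)


def random_tree(seed: int, n_nodes: int = 100) -> TaxonomyTree:
    """Random parent-pointer tree (all ``no_rank``) for oracle tests."""
    rng = np.random.default_rng(seed)
    nodes = [TaxonomyNode(1, 1, NO_RANK, "root")]
    for taxid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, taxid))
        nodes.append(TaxonomyNode(taxid, parent, NO_RANK, f"n{taxid}"))
    return TaxonomyTree(nodes)


def lca_oracle(tree: TaxonomyTree, taxids) -> int:
    """Independent LCA: longest common prefix of root-first lineages."""
    lineages = [tree.lineage(t) for t in taxids]
    deepest = None
    for level in zip(*lineages):
        if len(set(level)) == 1:
            deepest = level[0]
        else:
            break
    return deepest
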