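"""Shared fixtures: toy taxonomies and random-tree builders."""

from __future__ import annotations

import numpy as np
import pytest

from bayeslca.taxonomy import TaxonomyTree


@pytest.fixture
def lacto_tree() -> TaxonomyTree:
    """A small Lactobacillus-style taxonomy with two congeneric species and
    an outgroup genus in a second phylum."""
    nodes = {
        "root": ("root", "no rank", None),
        "k1": ("Bacteria", "superkingdom", "root"),
        "p1": ("Firmicutes", "phylum", "k1"),
        "c1": ("Bacilli", "class", "p1"),
        "o1": ("Lactobacillales", "order", "c1"),
        "f1": ("Lactobacillaceae", "family", "o1"),
        "g1": ("Lactobacillus", "genus", "f1"),
        "s1": ("Lactobacillus acidophilus", "species", "g1"),
        "s2": ("Lactobacillus casei", "species", "g1"),
        "p2": ("Proteobacteria", "phylum", "k1"),
        "c2": ("Gammaproteobacteria", "class", "p2"),
        "o2": ("Enterobacterales", "order", "c2"),
        "f2": ("Enterobacteriaceae", "family", "o2"),
        "g2": ("Escherichia", "genus", "f2"),
        "s3": ("Escherichia coli", "species", "g2"),
    }
    return TaxonomyTree(nodes)


def random_taxonomy(rng: np.random.Generator, n_leaves: int = 10) -> tuple[TaxonomyTree, list[str]]:
    """A random rank-complete taxonomy with ``n_leaves`` species leaves.

    Each leaf gets a random lineage through a small pool of internal nodes
    per rank, so leaves share ancestors unpredictably.
    """
    ranks = ("phylum", "class", "order", "family", "genus", "species")
    nodes: dict[str, tuple[str, str, str | None]] = {"root": ("root", "no rank", None)}
    leaves = []
    for i in range(n_leaves):
        parent = "root"
        path = ""
        for rank in ranks[:-1]:
            # small pools force shared internal nodes
            choice = int(rng.integers(0, 2))
            path = f"{path}/{rank[0]}{choice}"
            if path not in nodes:
                nodes[path] = (path, rank, parent)
            parent = path
        leaf = f"leaf{i}"
        nodes[leaf] = (leaf, "species", parent)
        leaves.append(leaf)
    return TaxonomyTree(nodes), leaves


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
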