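"""Rank-labelled taxonomy trees: lineage lookup, LCA, and leaf-to-rank summation.

The classifier assigns each query a posterior probability over candidate
*leaf* taxa (the taxa annotating individual database hits).  Everything at
higher taxonomic levels — genus, family, ... phylum — is obtained by summing
leaf-level quantities over the descendants of each internal node.  This
module owns that machinery: a rooted, rank-labelled tree plus

* ``lineage_of``   — the canonical-rank lineage of a taxon,
* ``lca``          — lowest common ancestor of a set of taxa,
* ``sum_to_rank``  — aggregate a leaf-keyed map of non-negative values onto
  the ancestors at a requested rank (used for both posterior probabilities
  and bootstrap confidence scores).

Trees can be built from NCBI taxonomy dumps (``nodes.dmp``/``names.dmp``)
or from a flat per-leaf lineage TSV (``taxid<TAB>rank:name;rank:name;...``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CANONICAL_RANKS",
    "RankedTaxon",
    "Lineage",
    "TaxonomyTree",
    "TaxonomyIntegrityError",
    "load_taxonomy",
    "load_lineage_tsv",
]

#: Canonical ranks reported by the classifier, root-most first.  ``subspecies``
#: is optional: it participates when present in the reference annotation.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "subspecies",
)

_RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}

NO_RANK = "no rank"


class TaxonomyIntegrityError(ValueError):
    """The node table does not describe a single rooted tree."""


class UnknownTaxonError(KeyError):
    """A taxid was looked up that is not present in the tree."""


@dataclass(frozen=True)
class RankedTaxon:
    rank: str
    taxid: str
    name: str


#: A lineage is an ordered sequence of canonical-rank taxa, root-most first.
Lineage = tuple[RankedTaxon, ...]


@dataclass(frozen=True)
class _Node:
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTree:
    """A rooted tree of taxa with rank labels.

    Parameters
    ----------
    nodes:
        Mapping ``taxid -> (name, rank, parent_taxid)``.  The root is the
        single node whose parent is ``None`` or itself (NCBI convention).
    """

    def __init__(self, nodes: Mapping[str, tuple[str, str, str | None]]):
        self._nodes: dict[str, _Node] = {}
        roots = []
        for taxid, (name, rank, parent) in nodes.items():
            if parent is None or parent == taxid:
                roots.append(taxid)
                parent = None
            self._nodes[str(taxid)] = _Node(name=name, rank=rank, parent=parent)
        if len(roots) != 1:
            raise TaxonomyIntegrityError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)!r}"
            )
        self.root: str = roots[0]
        self._validate()
        self._children: dict[str, list[str]] = {t: [] for t in self._nodes}
        for taxid, node in self._nodes.items():
            if node.parent is not None:
                self._children[node.parent].append(taxid)

    # -- construction checks -------------------------------------------------

    def _validate(self) -> None:
        orphans = sorted(
            t for t, n in self._nodes.items() if n.parent is not None and n.parent not in self._nodes
        )
        if orphans:
            raise TaxonomyIntegrityError(
                f"orphan nodes (parent taxid absent): {orphans[:10]!r}"
            )
        # Walk every node to the root; a node revisited within one walk is a cycle.
        seen_ok: set[str] = {self.root}
        for start in self._nodes:
            path = []
            t: str | None = start
            on_path = set()
            while t is not None and t not in seen_ok:
                if t in on_path:
                    raise TaxonomyIntegrityError(f"cycle detected through taxid {t!r}")
                on_path.add(t)
                path.append(t)
                t = self._nodes[t].parent
            seen_ok.update(path)

    # -- basic lookups -------------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def name(self, taxid: str) -> str:
        return self._node(taxid).name

    def rank(self, taxid: str) -> str:
        return self._node(taxid).rank

    def parent(self, taxid: str) -> str | None:
        return self._node(taxid).parent

    def children(self, taxid: str) -> Sequence[str]:
        self._node(taxid)
        return tuple(self._children[taxid])

    def leaves(self) -> list[str]:
        return [t for t, ch in self._children.items() if not ch]

    def _node(self, taxid: str) -> _Node:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(f"taxid {taxid!r} not present in the taxonomy") from None

    # -- lineage / LCA -------------------------------------------------------

    def path_to_root(self, taxid: str) -> list[str]:
        """Taxids from ``taxid`` up to and including the root."""
        path = [taxid]
        node = self._node(taxid)
        while node.parent is not None:
            path.append(node.parent)
            node = self._nodes[node.parent]
        return path

    def lineage_of(self, taxid: str) -> Lineage:
        """Canonical-rank lineage of ``taxid``, root-most first.

        Nodes labelled ``"no rank"`` (or any rank outside the canonical set)
        are transparent: they are skipped, so the result contains only
        canonical ranks in strictly descending order.
        """
        out = []
        for t in self.path_to_root(taxid):
            node = self._nodes[t]
            if node.rank in _RANK_DEPTH:
                out.append(RankedTaxon(rank=node.rank, taxid=t, name=node.name))
        out.reverse()
        return tuple(out)

    def ancestor_at(self, taxid: str, rank: str) -> str | None:
        """The ancestor (or the node itself) carrying ``rank``; None if absent."""
        if rank not in _RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}; canonical ranks are {CANONICAL_RANKS}")
        for t in self.path_to_root(taxid):
            if self._nodes[t].rank == rank:
                return t
        return None

    def lca(self, taxids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxids."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca() requires a non-empty set of taxids")
        paths = [list(reversed(self.path_to_root(t))) for t in taxids]
        lca = self.root
        for level in zip(*paths):
            if all(t == level[0] for t in level):
                lca = level[0]
            else:
                break
        return lca

    # -- aggregation ---------------------------------------------------------

    def sum_to_rank(self, leaf_values: Mapping[str, float], rank: str) -> dict[str, float]:
        """Sum leaf-keyed non-negative values onto their ancestors at ``rank``.

        For every internal node *I* at the requested rank, the output value is
        the sum over its descendant leaves present in ``leaf_values``.  Leaves
        whose lineage has no node at ``rank`` (e.g. an annotation stopping at
        genus when species sums are requested) contribute to no output entry.
        """
        if rank not in _RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}; canonical ranks are {CANONICAL_RANKS}")
        out: dict[str, float] = {}
        for taxid, value in leaf_values.items():
            if value < 0:
                raise ValueError(f"negative value {value!r} for taxid {taxid!r}")
            anc = self.ancestor_at(taxid, rank)
            if anc is not None:
                out[anc] = out.get(anc, 0.0) + float(value)
        return out


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def _split_dmp_line(line: str) -> list[str]:
    # NCBI dump rows are "<f1>\t|\t<f2>\t|\t...\t|\n"
    return [f.strip() for f in line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")]


def load_taxonomy(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Build a tree from NCBI-dump-dialect ``nodes.dmp`` and ``names.dmp``.

    The root is recognised by the NCBI convention of being its own parent.
    Only rows of name class ``scientific name`` are used for node names.
    """
    parents: dict[str, tuple[str, str]] = {}
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyIntegrityError(
                    f"{nodes_path}: malformed nodes.dmp row: {line!r}"
                )
            taxid, parent, rank = fields[0], fields[1], fields[2]
            parents[taxid] = (parent, rank)
    names: dict[str, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 4 or fields[3] != "scientific name":
                continue
            names[fields[0]] = fields[1]
    nodes = {
        taxid: (names.get(taxid, taxid), rank, parent)
        for taxid, (parent, rank) in parents.items()
    }
    return TaxonomyTree(nodes)


def load_lineage_tsv(path: str | Path) -> TaxonomyTree:
    """Build a tree from a flat lineage TSV.

    Each line is ``taxid<TAB>rank1:name1;rank2:name2;...`` with ranks in
    root-to-leaf canonical order; the given taxid becomes the leaf node for
    the last entry.  Internal nodes are shared between lines via their full
    name path, so two phyla that happen to share a genus name stay distinct.
    Lineages missing intermediate canonical ranks are accepted; a warning
    lists the affected taxids.
    """
    nodes: dict[str, tuple[str, str, str | None]] = {
        "root": ("root", NO_RANK, None)
    }
    flagged: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                taxid, lineage_str = line.split("\t")
            except ValueError:
                raise TaxonomyIntegrityError(
                    f"{path}:{lineno}: expected 'taxid<TAB>lineage'"
                ) from None
            pairs = []
            for item in lineage_str.split(";"):
                if not item:
                    continue
                rank, _, name = item.partition(":")
                if not name:
                    raise TaxonomyIntegrityError(
                        f"{path}:{lineno}: lineage item {item!r} is not 'rank:name'"
                    )
                pairs.append((rank.strip(), name.strip()))
            if not pairs:
                raise TaxonomyIntegrityError(f"{path}:{lineno}: empty lineage")
            depths = [_RANK_DEPTH.get(r, -1) for r, _ in pairs]
            if any(d < 0 for d in depths):
                bad = [r for r, d in zip((r for r, _ in pairs), depths) if d < 0]
                raise TaxonomyIntegrityError(
                    f"{path}:{lineno}: unknown rank(s) {bad!r}"
                )
            if depths != sorted(depths) or len(set(depths)) != len(depths):
                raise TaxonomyIntegrityError(
                    f"{path}:{lineno}: ranks not in strictly descending canonical order"
                )
            expected = list(range(depths[0], depths[0] + len(depths)))
            if depths != expected:
                flagged.append(taxid)
            parent = "root"
            # internal nodes keyed by their full name path
            for rank, name in pairs[:-1]:
                node_id = f"{parent}|{name}" if parent != "root" else f"root|{name}"
                if node_id not in nodes:
                    nodes[node_id] = (name, rank, parent)
                parent = node_id
            leaf_rank, leaf_name = pairs[-1]
            if taxid in nodes:
                raise TaxonomyIntegrityError(
                    f"{path}:{lineno}: duplicate taxid {taxid!r}"
                )
            nodes[taxid] = (leaf_name, leaf_rank, parent)
    if flagged:
        warnings.warn(
            f"{len(flagged)} lineage(s) skip intermediate canonical ranks "
            f"(e.g. {flagged[:5]!r}); missing ranks will be reported as unclassified",
            stacklevel=2,
        )
    return TaxonomyTree(nodes)
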