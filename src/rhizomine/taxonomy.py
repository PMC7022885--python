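"""Ranked taxonomy tree with lineage and lowest-common-ancestor queries.

The tree is the substrate of read classification: short-read alignment
hits name subject taxa, and ambiguous reads are promoted to the lowest
common ancestor (LCA) of their hits.  It also backs rank aggregation
(e.g. grouping species-level counts into families) and contaminant
removal by lineage.

Two input dialects are supported: the pipe-delimited ``nodes.dmp`` /
``names.dmp`` dump convention, and a simplified four-column TSV
(``taxid  parent  rank  name``) convenient for fixtures and synthetic
trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

#: Canonical rank labels, root-most first.  ``no_rank`` may repeat along a
#: path; every other label appears at most once per lineage.
RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NO_RANK = "no_rank"

#: NCBI taxids of the lineages the pipeline treats as host/animal
#: contamination in a plant root meta-transcriptome.
VIRIDIPLANTAE_TAXID = 33090
METAZOA_TAXID = 33208

PathLike = Union[str, Path]


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (orphan, cycle, duplicate)."""


class UnknownTaxidError(KeyError):
    """A query named a taxid that is not present in the tree."""

    def __init__(self, taxid: int):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:  # KeyError quotes its arg; be explicit
        return f"taxid {self.taxid} is not in the taxonomy"


@dataclass(frozen=True)
class TaxonomyNode:
    """One taxon: identity, parent pointer, rank and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Parent-pointer tree over integer taxids.

    Parameters
    ----------
    nodes:
        Mapping or iterable of :class:`TaxonomyNode`.  Exactly one node
        must be its own parent (the root).  Every other parent must be
        present: orphans are a :class:`TaxonomyError`, never silently
        re-rooted.
    root_taxid:
        Optional explicit root.  When given it must match the
        self-parented node.
    """

    def __init__(
        self,
        nodes: Union[Mapping[int, TaxonomyNode], Iterable[TaxonomyNode]],
        root_taxid: Optional[int] = None,
    ):
        if isinstance(nodes, Mapping):
            node_list = list(nodes.values())
        else:
            node_list = list(nodes)
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in node_list:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node

        roots = [n.taxid for n in node_list if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one self-parented root, found {len(roots)}"
            )
        self.root_taxid = roots[0]
        if root_taxid is not None and root_taxid != self.root_taxid:
            raise TaxonomyError(
                f"declared root {root_taxid} is not the self-parented node "
                f"{self.root_taxid}"
            )

        for node in node_list:
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"orphan node {node.taxid}: parent {node.parent_taxid} "
                    "is absent"
                )

        self._depth: dict[int, int] = {}
        self._compute_depths()
        self._check_rank_uniqueness()

    # -- validation -----------------------------------------------------

    def _compute_depths(self) -> None:
        """Depth of every node; walking parents past ``len(nodes)`` steps
        means a cycle."""
        limit = len(self.nodes)
        for taxid in self.nodes:
            path = []
            current = taxid
            steps = 0
            while current not in self._depth and current != self.root_taxid:
                path.append(current)
                current = self.nodes[current].parent_taxid
                steps += 1
                if steps > limit:
                    raise TaxonomyError(f"cycle detected at taxid {taxid}")
            base = 0 if current == self.root_taxid else self._depth[current]
            self._depth[self.root_taxid] = 0
            for offset, node in enumerate(reversed(path), start=1):
                self._depth[node] = base + offset

    def _check_rank_uniqueness(self) -> None:
        for taxid, node in self.nodes.items():
            if node.rank == NO_RANK:
                continue
            current = node.parent_taxid
            while True:
                if self.nodes[current].rank == node.rank and current != taxid:
                    raise TaxonomyError(
                        f"rank '{node.rank}' repeats on the lineage of "
                        f"taxid {taxid}"
                    )
                if current == self.root_taxid:
                    break
                current = self.nodes[current].parent_taxid

    # -- queries ---------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxid: int) -> TaxonomyNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def depth(self, taxid: int) -> int:
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        return self._depth[taxid]

    def lineage(self, taxid: int) -> list[int]:
        """Root-first path of taxids ending at ``taxid``."""
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        path = [taxid]
        current = taxid
        while current != self.root_taxid:
            current = self.nodes[current].parent_taxid
            path.append(current)
        path.reverse()
        return path

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxids.

        The result lies on every input lineage and is the deepest such
        node; ``lca({x}) == x``.
        """
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty set is undefined")
        for t in taxids:
            if t not in self.nodes:
                raise UnknownTaxidError(t)
        # Walk all inputs up to a common depth, then in lock-step.
        depths = {t: self._depth[t] for t in set(taxids)}
        current = set(depths)
        d = min(depths.values())
        current = {self._ancestor_at_depth(t, d) for t in current}
        while len(current) > 1:
            current = {self.nodes[t].parent_taxid for t in current}
        return current.pop()

    def _ancestor_at_depth(self, taxid: int, depth: int) -> int:
        current = taxid
        while self._depth[current] > depth:
            current = self.nodes[current].parent_taxid
        return current

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """The unique lineage node with rank ``rank``, or ``None``.

        A lineage lacking the rank yields ``None`` rather than being
        promoted to the nearest available rank: silent promotion would
        distort rank-aggregated count tables.
        """
        if rank not in RANKS and rank != NO_RANK:
            raise ValueError(f"unrecognized rank label '{rank}'")
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        for ancestor in self.lineage(taxid):
            if self.nodes[ancestor].rank == rank:
                return ancestor
        return None

    def is_descendant_of(self, taxid: int, ancestor: int) -> bool:
        return ancestor in self.lineage(taxid)


# -- loading -------------------------------------------------------------


def _parse_dump_row(line: str) -> list[str]:
    # dump rows look like "1\t|\t1\t|\tno rank\t|" with a trailing delimiter
    return [field.strip() for field in line.rstrip("\n").rstrip("\t|").split("\t|\t")]


def load_taxonomy(
    nodes_source: PathLike,
    names_source: Optional[PathLike] = None,
) -> TaxonomyTree:
    """Load a tree from pipe-delimited ``nodes.dmp`` / ``names.dmp`` dumps.

    Only the first three fields of each nodes row (taxid, parent, rank)
    are used; names rows contribute the ``scientific name`` entry.
    Rank labels are normalised by replacing spaces with underscores
    (``no rank`` -> ``no_rank``).  Unrecognised rank labels are kept as
    ``no_rank`` so that clade-level dump entries do not break the
    rank-uniqueness invariant.
    """
    names: dict[int, str] = {}
    if names_source is not None:
        with open(names_source) as handle:
            for line in handle:
                if not line.strip():
                    continue
                fields = _parse_dump_row(line)
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]

    nodes = []
    with open(nodes_source) as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _parse_dump_row(line)
            taxid = int(fields[0])
            parent = int(fields[1])
            rank = fields[2].replace(" ", "_")
            if rank not in RANKS:
                rank = NO_RANK
            nodes.append(
                TaxonomyNode(
                    taxid=taxid,
                    parent_taxid=parent,
                    rank=rank,
                    name=names.get(taxid, ""),
                )
            )
    return TaxonomyTree(nodes)


def load_taxonomy_tsv(source: PathLike) -> TaxonomyTree:
    """Load the simplified 4-column TSV dialect (taxid, parent, rank, name)."""
    nodes = []
    with open(source) as handle:
        for line in handle:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TaxonomyError(f"malformed taxonomy row: {line!r}")
            name = fields[3] if len(fields) > 3 else ""
            nodes.append(
                TaxonomyNode(
                    taxid=int(fields[0]),
                    parent_taxid=int(fields[1]),
                    rank=fields[2],
                    name=name,
                )
            )
    return TaxonomyTree(nodes)


def write_taxonomy_tsv(tree: TaxonomyTree, path: PathLike) -> None:
    with open(path, "w") as handle:
        for taxid in sorted(tree.nodes):
            node = tree.nodes[taxid]
            handle.write(
                f"{node.taxid}\t{node.parent_taxid}\t{node.rank}\t{node.name}\n"
            )


def load_merged(source: PathLike) -> dict[int, int]:
    """Load an old->new taxid remapping table (``merged.dmp`` dialect)."""
    mapping: dict[int, int] = {}
    with open(source) as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _parse_dump_row(line)
            mapping[int(fields[0])] = int(fields[1])
    return mapping


def remap_taxids(
    tree: TaxonomyTree,
    taxids: Sequence[int],
    merged: Optional[Mapping[int, int]] = None,
) -> tuple[list[int], int]:
    """Resolve possibly stale taxids against the tree.

    Taxids absent from the tree are first looked up in the optional
    merged-id table; those that still cannot be placed are dropped and
    counted (the count is also logged as a warning).
    """
    merged = merged or {}
    kept: list[int] = []
    dropped = 0
    for taxid in taxids:
        if taxid in tree:
            kept.append(taxid)
        elif taxid in merged and merged[taxid] in tree:
            kept.append(merged[taxid])
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d taxids not resolvable in the taxonomy", dropped)
    return kept, dropped
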