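"""Taxonomic lineage model used for resolution comparison and reconciliation.

A :class:`TaxonomyTree` is a rank-labelled forest over the seven Linnaean
ranks (kingdom > phylum > class > order > family > genus > species).
Detections that could not be told apart morphologically (e.g. "rudd/roach")
are represented as :class:`MorphCategory` composites whose members are tree
nodes; reconciliation logic treats a record's *scope* as the set of nodes it
could refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Ordered rank ladder, coarsest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for unknown ids, rank violations or malformed lineage input."""


@dataclass(frozen=True)
class TaxonNode:
    id: str
    name: str
    rank: str
    parent_id: str | None = None
    #: set when the source lineage used an intermediate rank (e.g. infraclass)
    #: that was attached at the nearest coarser ladder rank
    off_ladder: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxon {self.id!r}")


class TaxonomyTree:
    """Immutable rank-labelled forest with ancestor/descendant queries.

    Parameters
    ----------
    nodes
        Iterable of :class:`TaxonNode`. Parent ranks must be strictly coarser
        than child ranks and ids unique; cycles are rejected.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise TaxonomyError(f"duplicate taxon id {node.id!r}")
            self._nodes[node.id] = node
        self._children: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"taxon {node.id!r} references unknown parent {node.parent_id!r}"
                )
            if RANK_DEPTH[parent.rank] >= RANK_DEPTH[node.rank]:
                raise TaxonomyError(
                    f"parent {parent.id!r} ({parent.rank}) not coarser than "
                    f"child {node.id!r} ({node.rank})"
                )
            self._children[parent.id].append(node.id)
        # rank ordering along each parent chain rules out cycles, but verify
        # reachability from roots explicitly
        seen: set[str] = set()
        stack = [nid for nid, n in self._nodes.items() if n.parent_id is None]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children[nid])
        if seen != set(self._nodes):
            orphans = sorted(set(self._nodes) - seen)
            raise TaxonomyError(f"nodes unreachable from any root: {orphans}")

    # -- basic queries ----------------------------------------------------
    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def ids(self) -> list[str]:
        return list(self._nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon id {taxon_id!r}") from None

    def children(self, taxon_id: str) -> list[str]:
        self.node(taxon_id)
        return list(self._children[taxon_id])

    def root_path(self, taxon_id: str) -> list[str]:
        """Ids from the root down to (and including) ``taxon_id``."""
        path = []
        cur: str | None = taxon_id
        while cur is not None:
            node = self.node(cur)
            path.append(cur)
            cur = node.parent_id
        path.reverse()
        return path

    def depth(self, taxon_id: str) -> int:
        return len(self.root_path(taxon_id)) - 1

    def ancestors(self, taxon_id: str) -> list[str]:
        """Proper ancestors, root first."""
        return self.root_path(taxon_id)[:-1]

    def subtree(self, taxon_id: str) -> set[str]:
        """Ids of ``taxon_id`` and all its descendants."""
        out: set[str] = set()
        stack = [taxon_id]
        self.node(taxon_id)
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(self._children[nid])
        return out

    def kingdom_of(self, taxon_id: str) -> str:
        return self.root_path(taxon_id)[0]

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor of a nonempty set of ids."""
        ids = list(taxon_ids)
        if not ids:
            raise TaxonomyError("lca of empty set")
        paths = [self.root_path(t) for t in ids]
        shortest = min(len(p) for p in paths)
        lca = None
        for i in range(shortest):
            level = {p[i] for p in paths}
            if len(level) == 1:
                lca = level.pop()
            else:
                break
        if lca is None:
            raise TaxonomyError(f"taxa {ids} share no common ancestor")
        return lca


def is_ancestor(a: str, b: str, tree: TaxonomyTree) -> bool:
    """True iff ``a`` is a proper ancestor of ``b`` (lies on b's root path, a != b)."""
    tree.node(a)
    if a == b:
        return False
    return a in tree.ancestors(b)


@dataclass(frozen=True)
class MorphCategory:
    """A possibly-composite identification, e.g. ``rudd/roach``.

    ``member_leaves`` holds the tree ids the identification could refer to;
    a single member makes the category equivalent to that taxon.
    """

    label: str
    member_leaves: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.member_leaves:
            raise TaxonomyError(f"category {self.label!r} has no members")

    def validate(self, tree: TaxonomyTree) -> None:
        for m in self.member_leaves:
            if m not in tree:
                raise TaxonomyError(
                    f"category {self.label!r} member {m!r} not in taxonomy"
                )
        if len(self.member_leaves) > 1:
            lca = tree.lca(self.member_leaves)
            if tree.node(lca).rank == "kingdom":
                raise TaxonomyError(
                    f"composite category {self.label!r} members share no ancestor "
                    "below kingdom"
                )


def category_index(categories: Iterable[MorphCategory]) -> dict[str, MorphCategory]:
    idx: dict[str, MorphCategory] = {}
    for cat in categories:
        if cat.label in idx:
            raise TaxonomyError(f"duplicate category label {cat.label!r}")
        idx[cat.label] = cat
    return idx


# -- TSV I/O ---------------------------------------------------------------

def read_taxonomy(path) -> TaxonomyTree:
    """Read a lineage table (TSV: id, name, rank, parent_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "name", "rank", "parent_id"}
    if not required.issubset(df.columns):
        raise TaxonomyError(f"taxonomy table needs columns {sorted(required)}")
    nodes = [
        TaxonNode(
            id=row.id,
            name=row.name,
            rank=row.rank,
            parent_id=row.parent_id or None,
            off_ladder=str(getattr(row, "off_ladder", "")).lower() in ("1", "true"),
        )
        for row in df.itertuples(index=False)
    ]
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    rows = [
        {
            "id": n.id,
            "name": n.name,
            "rank": n.rank,
            "parent_id": n.parent_id or "",
            "off_ladder": int(n.off_ladder),
        }
        for n in (tree.node(i) for i in tree.ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_categories(path) -> dict[str, MorphCategory]:
    """Read composite categories (TSV: label, members as comma-separated ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cats = [
        MorphCategory(row.label, frozenset(m.strip() for m in row.members.split(",")))
        for row in df.itertuples(index=False)
    ]
    return category_index(cats)


def write_categories(categories: Mapping[str, MorphCategory], path) -> None:
    rows = [
        {"label": c.label, "members": ",".join(sorted(c.member_leaves))}
        for c in categories.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
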