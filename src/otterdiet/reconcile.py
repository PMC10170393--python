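"""Reconciliation of prey detections across markers and methods.

Two detection channels rarely agree exactly: a vertebrate-targeted 16S assay
may call *Salmo trutta* where COI only reaches Salmonidae, and hard-part
morphology may stop at a composite such as "rudd/roach".  The rules here
merge such detections per sample, always keeping the finest identification
that is certainly correct, and record for every retained presence whether it
came from one channel, both at the same resolution, or both at different
resolutions.

A record's *scope* is the set of taxonomy nodes it could refer to (one node
for an unambiguous call, several for a composite).  Record X is at least as
fine as Y when every node in X's scope falls inside the subtree of some node
in Y's scope; strictly-finer records absorb coarser ones, and partial
overlaps collapse to the lowest common ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .taxonomy import MorphCategory, TaxonomyError, TaxonomyTree

logger = logging.getLogger(__name__)

PROVENANCES = ("only_A", "only_B", "both_same_rank", "both_diff_rank")

#: morphological identifications attributed to secondary predation or grooming
DEFAULT_SECONDARY_BLOCKLIST = frozenset(
    {"insect", "beetle", "mollusk", "snail", "mammal"}
)


@dataclass(frozen=True)
class PresenceRecord:
    """A binary prey detection in one sample from one channel."""

    sample_id: str
    taxon: str  # tree node id or MorphCategory label
    channel: str  # marker16S | markerCOI | morphology | combined
    provenance: str | None = None

    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.taxon)


def resolve_scope(
    taxon: str,
    tree: TaxonomyTree,
    categories: Mapping[str, MorphCategory] | None = None,
) -> frozenset[str]:
    """Scope of a record label: its tree node, or a composite's members."""
    if categories and taxon in categories:
        cat = categories[taxon]
        cat.validate(tree)
        return frozenset(cat.member_leaves)
    if taxon in tree:
        return frozenset({taxon})
    raise TaxonomyError(f"taxon {taxon!r} is neither a tree id nor a known category")


class _ScopeAlgebra:
    """Fine/coarse/overlap relations between scopes, with subtree caching."""

    def __init__(self, tree: TaxonomyTree):
        self.tree = tree
        self._subtrees: dict[str, set[str]] = {}

    def subtree(self, node: str) -> set[str]:
        st = self._subtrees.get(node)
        if st is None:
            st = self.tree.subtree(node)
            self._subtrees[node] = st
        return st

    def at_least_as_fine(self, x: frozenset[str], y: frozenset[str]) -> bool:
        return all(any(a in self.subtree(b) for b in y) for a in x)

    def overlaps(self, x: frozenset[str], y: frozenset[str]) -> bool:
        return any(
            a in self.subtree(b) or b in self.subtree(a) for a in x for b in y
        )


@dataclass
class _Item:
    label: str
    scope: frozenset[str]
    direct: set[str]  # channel tags where this exact label was recorded
    absorbed: set[str]  # channel tags folded in via absorption or LCA collapse

    @property
    def channels(self) -> set[str]:
        return self.direct | self.absorbed


def _provenance(item: _Item) -> str:
    if {"A", "B"} <= item.direct:
        return "both_same_rank"
    if {"A", "B"} <= item.channels:
        return "both_diff_rank"
    return "only_A" if "A" in item.channels else "only_B"


def _reduce_sample(
    labelled: Sequence[tuple[str, str]],  # (label, channel tag "A"/"B")
    tree: TaxonomyTree,
    algebra: _ScopeAlgebra,
    categories: Mapping[str, MorphCategory] | None,
    collapse_partial: bool,
) -> list[_Item]:
    # group identical labels across channels
    by_label: dict[str, _Item] = {}
    for label, tag in labelled:
        item = by_label.get(label)
        if item is None:
            by_label[label] = _Item(
                label, resolve_scope(label, tree, categories), {tag}, set()
            )
        else:
            item.direct.add(tag)
    items = [by_label[k] for k in sorted(by_label)]

    changed = True
    while changed:
        changed = False
        n = len(items)
        for i in range(n):
            for j in range(i + 1, n):
                x, y = items[i], items[j]
                xy = algebra.at_least_as_fine(x.scope, y.scope)
                yx = algebra.at_least_as_fine(y.scope, x.scope)
                if xy and yx:
                    # same resolution under different labels: keep one label,
                    # preferring a plain tree id for determinism
                    keep, drop = (x, y) if x.label in tree else (y, x)
                    if x.label in tree and y.label in tree:
                        keep, drop = (x, y) if x.label <= y.label else (y, x)
                    keep.direct |= drop.direct
                    keep.absorbed |= drop.absorbed
                    items = [it for it in items if it is not drop]
                elif xy:  # x strictly finer: absorbs y
                    x.absorbed |= y.channels
                    items = [it for it in items if it is not y]
                elif yx:
                    y.absorbed |= x.channels
                    items = [it for it in items if it is not x]
                elif collapse_partial and algebra.overlaps(x.scope, y.scope):
                    lca = tree.lca(set(x.scope) | set(y.scope))
                    merged = _Item(
                        lca, frozenset({lca}), set(), x.channels | y.channels
                    )
                    items = [it for it in items if it is not x and it is not y]
                    items.append(merged)
                    items.sort(key=lambda it: it.label)
                else:
                    continue
                changed = True
                break
            if changed:
                break
    return items


def _merge_channels(
    a: Iterable[PresenceRecord],
    b: Iterable[PresenceRecord],
    tree: TaxonomyTree,
    categories: Mapping[str, MorphCategory] | None,
    collapse_partial: bool,
) -> list[PresenceRecord]:
    algebra = _ScopeAlgebra(tree)
    per_sample: dict[str, list[tuple[str, str]]] = {}
    for rec in a:
        per_sample.setdefault(rec.sample_id, []).append((rec.taxon, "A"))
    for rec in b:
        per_sample.setdefault(rec.sample_id, []).append((rec.taxon, "B"))
    out: list[PresenceRecord] = []
    for sample_id in sorted(per_sample):
        for item in _reduce_sample(
            per_sample[sample_id], tree, algebra, categories, collapse_partial
        ):
            out.append(
                PresenceRecord(
                    sample_id, item.label, "combined", _provenance(item)
                )
            )
    return out


def merge_marker_presences(
    p16s: Iterable[PresenceRecord],
    pcoi: Iterable[PresenceRecord],
    tree: TaxonomyTree,
    categories: Mapping[str, MorphCategory] | None = None,
) -> list[PresenceRecord]:
    """Merge the two marker channels per sample.

    A taxon present in either marker is present in the merged set; when one
    marker's call is an ancestor of the other's, only the finer call is kept.
    Disjoint lineages in one sample are both kept (multi-prey samples are
    real).  Provenance is set per output record with the 16S channel as A.
    """
    return _merge_channels(p16s, pcoi, tree, categories, collapse_partial=False)


def combine_methods(
    dna: Iterable[PresenceRecord],
    morph: Iterable[PresenceRecord],
    tree: TaxonomyTree,
    categories: Mapping[str, MorphCategory] | None = None,
) -> list[PresenceRecord]:
    """Combine molecular and morphological detections per sample.

    Same-lineage detections keep the finer call; a composite containing the
    other channel's taxon resolves to that taxon (or to the composite's single
    member when that member is strictly finer); genuinely ambiguous partial
    overlaps collapse to the lowest common ancestor, the most specific taxon
    that is certainly correct.  Secondary-prey categories should be removed
    from the morphology channel first (:func:`remove_secondary`).  DNA is
    channel A for provenance.
    """
    return _merge_channels(dna, morph, tree, categories, collapse_partial=True)


def remove_secondary(
    morph: Iterable[PresenceRecord],
    blocklist: frozenset[str] | set[str] = DEFAULT_SECONDARY_BLOCKLIST,
) -> list[PresenceRecord]:
    """Drop morphological identifications attributed to secondary predation.

    The default blocklist covers broad invertebrate remains likely consumed
    inside primary prey, and fur-based "mammal" calls confounded by the
    predator grooming itself.
    """
    morph = list(morph)
    kept = [rec for rec in morph if rec.taxon not in blocklist]
    dropped = len(morph) - len(kept)
    if dropped:
        logger.info("remove_secondary: dropped %d blocklisted records", dropped)
    return kept


def partition_stats(
    a: Iterable[PresenceRecord],
    b: Iterable[PresenceRecord],
    tree: TaxonomyTree,
    categories: Mapping[str, MorphCategory] | None = None,
    collapse_partial: bool = False,
) -> dict:
    """Occurrence/taxon partition of two channels over shared samples.

    Returns per-provenance occurrence counts (disjoint; summing to the
    combined record total), per-provenance distinct-taxon counts (a taxon may
    appear under several provenances across samples), and combined totals.
    """
    combined = _merge_channels(a, b, tree, categories, collapse_partial)
    occ = {p: 0 for p in PROVENANCES}
    taxa: dict[str, set[str]] = {p: set() for p in PROVENANCES}
    for rec in combined:
        occ[rec.provenance] += 1
        taxa[rec.provenance].add(rec.taxon)
    return {
        "occurrences": occ,
        "taxa": {p: len(t) for p, t in taxa.items()},
        "combined_occurrences": len(combined),
        "combined_taxa": len({rec.taxon for rec in combined}),
    }


def records_from_matrix(df, channel: str) -> list[PresenceRecord]:
    """Long-form records from a binary sample x taxon DataFrame."""
    out = []
    for sample_id, row in df.iterrows():
        for taxon, v in row.items():
            if v:
                out.append(PresenceRecord(str(sample_id), str(taxon), channel))
    return out


def records_to_frame(records: Iterable[PresenceRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "taxon": r.taxon,
                "channel": r.channel,
                "provenance": r.provenance or "",
            }
            for r in records
        ],
        columns=["sample_id", "taxon", "channel", "provenance"],
    )


def records_from_frame(df, channel: str | None = None) -> list[PresenceRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PresenceRecord(
                str(row.sample_id),
                str(row.taxon),
                channel or str(row.channel),
                getattr(row, "provenance", None) or None,
            )
        )
    return out
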