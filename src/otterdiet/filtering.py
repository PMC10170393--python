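"""Post-bioinformatic filtering of per-marker read tables.

Amplicon read tables carry low-level noise: index hopping ("tag jumping")
moves reads between samples, and reagent or lab contamination shows up in
extraction/PCR negatives and in deliberately unused tag combinations.  Two
filters turn raw counts into defensible presences:

1. a *proportional* filter zeroing any count below a marker-specific
   fraction of its sample's raw total (strictly below; a count exactly at
   the threshold is retained), and
2. a *control* filter zeroing any count less than or equal to the maximum
   count of that taxon across all negative controls and unused tag
   combinations.

The proportional filter runs first on raw totals; the control filter second;
the proportional filter is not re-applied.  Both filters touch fecal and
mock samples only — control samples are the evidence, not the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reconcile import PresenceRecord, resolve_scope
from .taxonomy import MorphCategory, TaxonomyTree

logger = logging.getLogger(__name__)

ROLES = ("fecal", "extraction_negative", "pcr_negative", "unused_tag", "mock")
CONTROL_ROLES = ("extraction_negative", "pcr_negative", "unused_tag")
#: default proportional thresholds: vertebrate 16S and invertebrate COI assays
DEFAULT_PROPORTIONAL = {"16S": 0.005, "COI": 0.003}


class FilterConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and nonfood rules for one filtering run."""

    proportional_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONAL)
    )
    allowed_kingdom: str = "Animalia"
    consumer_taxon: str = "Lutra_lutra"
    #: taxa too coarse to be informative (e.g. an infraclass covering all
    #: plausible mammal prey and the predator alike)
    coarse_blocklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for marker, theta in self.proportional_thresholds.items():
            if not (0.0 < theta < 1.0):
                raise FilterConfigError(
                    f"proportional threshold for {marker!r} must lie in (0, 1), "
                    f"got {theta}"
                )

    def threshold_for(self, marker: str) -> float:
        try:
            return self.proportional_thresholds[marker]
        except KeyError:
            raise FilterConfigError(
                f"no proportional threshold configured for marker {marker!r}"
            ) from None


class ReadTable:
    """Sample x taxon read counts for one marker, with sample roles.

    Parameters
    ----------
    marker
        Marker name, e.g. ``"16S"`` or ``"COI"``.
    counts
        Nonnegative integer DataFrame; rows are samples, columns taxa.
    roles
        Series mapping each sample to one of :data:`ROLES`.
    """

    def __init__(self, marker: str, counts: pd.DataFrame, roles: pd.Series):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in read table")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("read counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        roles = roles.reindex(counts.index)
        if roles.isna().any():
            missing = list(counts.index[roles.isna()])
            raise ValueError(f"samples missing a role: {missing}")
        bad = sorted(set(roles) - set(ROLES))
        if bad:
            raise ValueError(f"unknown sample roles {bad}; expected one of {ROLES}")
        self.marker = marker
        self.counts = counts.astype(np.int64)
        self.roles = roles.astype(str)

    def samples_with_role(self, *roles: str) -> pd.Index:
        return self.counts.index[self.roles.isin(roles)]

    @property
    def fecal_samples(self) -> pd.Index:
        return self.samples_with_role("fecal")

    def _replaced(self, counts: pd.DataFrame) -> "ReadTable":
        return ReadTable(self.marker, counts, self.roles)


def collapse_repeats(table: ReadTable, repeat_of: Mapping[str, str]) -> ReadTable:
    """Collapse repeat samples onto their base sample by per-cell maximum.

    ``repeat_of`` maps repeat sample ids to the base sample id they re-assay;
    the maximum preserves every detection either PCR produced.
    """
    base = pd.Series(
        [repeat_of.get(s, s) for s in table.counts.index], index=table.counts.index
    )
    counts = table.counts.groupby(base).max()
    roles = table.roles.groupby(base).first()
    return ReadTable(table.marker, counts, roles)


def apply_proportional_filter(table: ReadTable, cfg: FilterConfig) -> ReadTable:
    """Zero counts strictly below ``theta x raw sample total`` in fecal/mock rows."""
    theta = cfg.threshold_for(table.marker)
    counts = table.counts.copy()
    target = table.samples_with_role("fecal", "mock")
    block = counts.loc[target]
    totals = block.sum(axis=1).to_numpy()[:, None]
    arr = block.to_numpy()
    arr = np.where(arr < theta * totals, 0, arr)
    counts.loc[target] = arr
    return table._replaced(counts)


def compute_control_thresholds(table: ReadTable) -> pd.Series:
    """Per-taxon maximum read count over negatives and unused tag combinations."""
    controls = table.samples_with_role(*CONTROL_ROLES)
    if len(controls) == 0:
        return pd.Series(0, index=table.counts.columns, dtype=np.int64)
    return table.counts.loc[controls].max(axis=0).astype(np.int64)


def apply_control_filter(table: ReadTable, thresholds: pd.Series) -> ReadTable:
    """Zero fecal/mock counts less than or equal to the per-taxon control maximum."""
    thr = thresholds.reindex(table.counts.columns).fillna(0).to_numpy()
    counts = table.counts.copy()
    target = table.samples_with_role("fecal", "mock")
    arr = counts.loc[target].to_numpy()
    arr = np.where(arr <= thr[None, :], 0, arr)
    counts.loc[target] = arr
    return table._replaced(counts)


def filter_table(table: ReadTable, cfg: FilterConfig) -> ReadTable:
    """Proportional filter on raw totals, then control filter."""
    prop = apply_proportional_filter(table, cfg)
    thresholds = compute_control_thresholds(prop)
    return apply_control_filter(prop, thresholds)


def to_presence(table: ReadTable, roles: tuple[str, ...] = ("fecal",)) -> pd.DataFrame:
    """Binary presence matrix (0/1 ints) over samples with the given roles."""
    rows = table.samples_with_role(*roles)
    return (table.counts.loc[rows] > 0).astype(np.int64)


def remove_nonfood(
    presences: Iterable[PresenceRecord],
    tree: TaxonomyTree,
    cfg: FilterConfig,
    traits: Mapping[str, bool] | pd.Series | None = None,
    categories: Mapping[str, MorphCategory] | None = None,
) -> tuple[list[PresenceRecord], dict[str, int]]:
    """Drop detections that cannot be food.

    Removes records outside the allowed kingdom (environmental DNA such as
    diatoms, fungi, bacteria), records of the consumer itself, records in the
    coarse-taxon blocklist, and records flagged small-bodied (< 3 mm maximum
    size, attributed to secondary or accidental ingestion).  Taxa lacking a
    trait entry are treated as not small, with a warning.

    Returns the retained records and a tally per removal class.
    """
    if traits is None:
        traits = {}
    if isinstance(traits, pd.Series):
        traits = traits.to_dict()
    tallies = {"non_animal": 0, "consumer": 0, "coarse": 0, "small_body": 0}
    kept: list[PresenceRecord] = []
    warned: set[str] = set()
    for rec in presences:
        scope = resolve_scope(rec.taxon, tree, categories)
        kingdoms = {tree.kingdom_of(t) for t in scope}
        if kingdoms != {cfg.allowed_kingdom}:
            tallies["non_animal"] += 1
            continue
        if rec.taxon == cfg.consumer_taxon or scope == {cfg.consumer_taxon}:
            tallies["consumer"] += 1
            continue
        if rec.taxon in cfg.coarse_blocklist:
            tallies["coarse"] += 1
            continue
        if rec.taxon not in traits and all(t in traits for t in scope):
            small = all(traits[t] for t in scope)
        elif rec.taxon in traits:
            small = bool(traits[rec.taxon])
        else:
            if rec.taxon not in warned:
                logger.warning(
                    "no body-size trait for %r; treating as not small", rec.taxon
                )
                warned.add(rec.taxon)
            small = False
        if small:
            tallies["small_body"] += 1
            continue
        kept.append(rec)
    removed = sum(tallies.values())
    if removed:
        logger.info("remove_nonfood: dropped %d records (%s)", removed, tallies)
    return kept, tallies


# -- I/O -------------------------------------------------------------------

def read_table_tsv(path, marker: str) -> ReadTable:
    """Read a wide TSV: sample_id, role, then one column per taxon."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("sample_id")
    roles = df.pop("role")
    return ReadTable(marker, df, roles)


def write_table_tsv(table: ReadTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "role", table.roles)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
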