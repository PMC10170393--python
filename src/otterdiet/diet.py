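"""Prey-group aggregation and occurrence statistics.

Taxa are aggregated into analyst-defined prey groups (by taxonomy,
morphology and ecological niche); a group is present in a sample if any of
its member taxa is.  Groups occurring in fewer than three samples are
treated as rare and removed before modelling.  Frequency of occurrence (FO)
is the percentage of samples containing a group; by default the denominator
is the number of samples in the matrix under analysis, i.e. samples with any
dietary data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: coarse identifications that cannot be placed in a prey group
DEFAULT_UNASSIGNED = frozenset({"Salmo_sp", "Cyprinid", "Bird"})


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class PreyGroupMap:
    """taxon id -> prey-group label, plus taxa that are dropped unassigned."""

    mapping: Mapping[str, str]
    unassigned: frozenset[str] = field(default_factory=lambda: DEFAULT_UNASSIGNED)

    def group_of(self, taxon: str) -> str | None:
        if taxon in self.mapping:
            return self.mapping[taxon]
        if taxon in self.unassigned:
            return None
        raise GroupingError(f"taxon {taxon!r} neither mapped to a group nor unassigned")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unassigned: Iterable[str] | None = None):
        mapping = dict(zip(df["taxon_id"].astype(str), df["group"].astype(str)))
        return cls(
            mapping,
            frozenset(unassigned) if unassigned is not None else DEFAULT_UNASSIGNED,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["taxon_id", "group"]
        )


def map_to_groups(m: pd.DataFrame, g: PreyGroupMap) -> pd.DataFrame:
    """Binary taxon matrix -> binary group matrix (logical OR over members)."""
    groups: dict[str, list[str]] = {}
    dropped = []
    for taxon in m.columns:
        label = g.group_of(str(taxon))
        if label is None:
            dropped.append(taxon)
        else:
            groups.setdefault(label, []).append(taxon)
    if dropped:
        n_presences = int(m[dropped].to_numpy().sum())
        logger.info(
            "map_to_groups: dropped %d unassigned taxa (%d presences): %s",
            len(dropped), n_presences, sorted(map(str, dropped)),
        )
    out = pd.DataFrame(index=m.index)
    for label in sorted(groups):
        out[label] = (m[groups[label]].sum(axis=1) > 0).astype(int)
    return out


def drop_rare_groups(m: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Remove group columns present in fewer than ``min_samples`` samples."""
    sums = m.sum(axis=0)
    rare = [c for c in m.columns if sums[c] < min_samples]
    if rare:
        logger.info("drop_rare_groups: removed %s", sorted(map(str, rare)))
    return m.drop(columns=rare)


def frequency_of_occurrence(m: pd.DataFrame) -> pd.Series:
    """Per-column FO as a percentage of the samples in ``m``."""
    if len(m) == 0:
        raise ValueError("presence matrix has no samples")
    return 100.0 * m.sum(axis=0) / len(m)


def mean_taxa_per_sample(m: pd.DataFrame) -> float:
    """Mean number of presences per sample (reported to 2 dp in summaries)."""
    if len(m) == 0:
        raise ValueError("presence matrix has no samples")
    return float(m.to_numpy().sum() / len(m))


def drop_empty_samples(m: pd.DataFrame) -> pd.DataFrame:
    """Restrict to samples with any dietary data (the default FO denominator)."""
    return m.loc[m.sum(axis=1) > 0]


def summarise(m: pd.DataFrame) -> dict:
    """FO table, mean presences per sample, totals — for a presence matrix."""
    fo = frequency_of_occurrence(m).sort_values(ascending=False)
    return {
        "n_samples": int(len(m)),
        "n_columns": int(m.shape[1]),
        "total_presences": int(m.to_numpy().sum()),
        "mean_per_sample": round(mean_taxa_per_sample(m), 2),
        "frequency_of_occurrence": {str(k): round(float(v), 1) for k, v in fo.items()},
    }
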