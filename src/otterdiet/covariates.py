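"""Per-individual biotic and spatial covariates.

Body condition is summarised by the scaled mass index
``SMI = M_i * (L0 / L_i) ** b``, where ``M_i`` and ``L_i`` are an
individual's mass and nose-to-tail length, ``L0`` the population mean
length, and ``b`` the slope of the standardised major axis (SMA) regression
of log mass on log length — ``b = sign(r) * sd(log M) / sd(log L)``.

Size classes come from Jenks natural breaks (the Fisher exact
dynamic-programming solution minimising within-class sum of squared
deviations), fitted separately per sex.  Spatial covariates are derived from
precomputed GIS summaries: river distance to the coast (mean over candidate
rivers; zero for coastal animals), and a primary water habitat assignment
where main river channels are weighted ten-fold against tributaries to
reflect their larger wetted cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SIZE_CLASSES = ("small", "medium", "large")
HABITATS = ("transitional", "lake", "main", "tributary")
#: month -> meteorological season (Dec-Feb winter, etc.)
SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


@dataclass(frozen=True)
class SmiParams:
    """Population mean length (mm) and SMA scaling exponent."""

    l0: float
    b_sma: float

    def __post_init__(self) -> None:
        if not self.l0 > 0:
            raise ValueError("L0 must be positive")
        if not np.isfinite(self.b_sma):
            raise ValueError("b_sma must be finite")


def fit_sma_exponent(masses: Sequence[float], lengths: Sequence[float]) -> float:
    """SMA slope of log mass on log length: sign(r) * sd(log M) / sd(log L)."""
    m = np.log(np.asarray(masses, dtype=float))
    l = np.log(np.asarray(lengths, dtype=float))
    if m.size < 3 or m.size != l.size:
        raise ValueError("need at least three paired observations")
    sd_l = l.std(ddof=1)
    if sd_l == 0:
        raise ValueError("lengths have zero variance")
    sd_m = m.std(ddof=1)
    r = np.corrcoef(m, l)[0, 1] if sd_m > 0 else 0.0
    return float(np.sign(r) * sd_m / sd_l) if sd_m > 0 else 0.0


def fit_smi_params(masses: Sequence[float], lengths: Sequence[float]) -> SmiParams:
    return SmiParams(
        l0=float(np.mean(lengths)), b_sma=fit_sma_exponent(masses, lengths)
    )


def smi(mass: float, length: float, params: SmiParams) -> float:
    """Scaled mass index in grams: ``mass * (L0 / length) ** b``."""
    if not length > 0:
        raise ValueError("length must be positive")
    return float(mass * (params.l0 / length) ** params.b_sma)


# -- Jenks natural breaks --------------------------------------------------

def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Class edges minimising total within-class sum of squared deviations.

    Returns ``k + 1`` edges ``[min, u_1, ..., u_{k-1}, max]`` where class
    ``i`` contains values in ``(edge_{i-1}, edge_i]`` (the first class is
    closed below).  Exact Fisher dynamic programme on the sorted values;
    ties among equally-good partitions are broken toward the lowest feasible
    break for reproducibility.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    n_distinct = np.unique(x).size
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must lie in [1, {n_distinct} distinct values], got {k}")

    # prefix sums for O(1) within-class SS of x[i:j]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ss(i: int, j: int) -> float:  # cost of class x[i:j], j exclusive
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = float("inf")
    # cost[c][j]: best cost of splitting x[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                # classes must not split ties across a break
                if i > 0 and x[i - 1] == x[i]:
                    continue
                cand = cost[c - 1][i] + ss(i, j)
                if cand < best - 1e-12:  # strict improvement; low break wins ties
                    best, arg = cand, i
            cost[c][j] = best
            back[c][j] = arg
    cuts = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c][j]
        cuts.append(j)
    cuts.reverse()  # [0, i_1, ..., n]
    edges = [float(x[0])]
    for c in range(1, k + 1):
        edges.append(float(x[cuts[c] - 1]))
    return edges


def classes_from_edges(values: Sequence[float], edges: Sequence[float]) -> np.ndarray:
    """Class index (0-based) per value for edges from :func:`jenks_breaks`."""
    x = np.asarray(values, dtype=float)
    inner = np.asarray(edges[1:-1], dtype=float)
    return np.searchsorted(inner, x, side="left")


def size_breaks_by_sex(
    lengths: Sequence[float], sexes: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Per-sex (lower, upper) bounds of the medium class from 3-class Jenks."""
    df = pd.DataFrame({"length": lengths, "sex": sexes})
    out: dict[str, tuple[float, float]] = {}
    for sex, grp in df.groupby("sex"):
        edges = jenks_breaks(grp["length"].to_numpy(), 3)
        cls = classes_from_edges(grp["length"].to_numpy(), edges)
        medium = grp["length"].to_numpy()[cls == 1]
        out[str(sex)] = (float(medium.min()), float(medium.max()))
    return out


def size_class(
    length: float, sex: str, breaks_by_sex: Mapping[str, tuple[float, float]]
) -> str:
    """small / medium / large; the medium interval is closed on both ends."""
    try:
        lo, hi = breaks_by_sex[sex]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}") from None
    if length < lo:
        return "small"
    if length <= hi:
        return "medium"
    return "large"


# -- spatial ---------------------------------------------------------------

@dataclass(frozen=True)
class SpatialInputs:
    """Precomputed GIS summaries for one individual (distances in km)."""

    otter_id: str
    candidate_river_distances: tuple[float, ...]
    within_1km_coast: bool
    closer_to_coast_than_river: bool
    dist_transitional: float
    dist_lake: float
    main_channel_length: float
    tributary_length: float


def river_distance(inp: SpatialInputs) -> float:
    """Mean river distance to the coast; zero for coastal individuals."""
    if inp.within_1km_coast and inp.closer_to_coast_than_river:
        return 0.0
    if not inp.candidate_river_distances:
        raise ValueError(f"otter {inp.otter_id!r}: no candidate river distances")
    return float(np.mean(inp.candidate_river_distances))


def assign_habitat(inp: SpatialInputs, proximity_km: float = 2.5) -> str:
    """Primary water habitat: transitional > lake > main/tributary.

    Individuals within ``proximity_km`` of transitional water (then of a
    lake) take that habitat; otherwise main channel iff the 10x-weighted
    main-channel share of buffer waterway length exceeds 50% (ties go to
    tributary).
    """
    if inp.dist_transitional <= proximity_km:
        return "transitional"
    if inp.dist_lake <= proximity_km:
        return "lake"
    weighted_main = 10.0 * inp.main_channel_length
    total = weighted_main + inp.tributary_length
    if total == 0:
        raise ValueError(
            f"otter {inp.otter_id!r}: no waterway length in buffer to classify"
        )
    return "main" if weighted_main / total > 0.5 else "tributary"


def season_from_month(month: int) -> str:
    if month not in SEASONS:
        raise ValueError(f"month must be 1..12, got {month}")
    return SEASONS[month]


def build_covariates(
    metadata: pd.DataFrame,
    spatial: Mapping[str, SpatialInputs],
    smi_params: SmiParams | None = None,
    reference_masses: Sequence[float] | None = None,
    reference_lengths: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Augment a metadata table with smi, size_class, season, coast_distance, habitat.

    ``metadata`` needs columns otter_id, sex, length_mm, mass_g, year, month,
    lat, lon, pct_urban.  The SMA exponent and mean length are taken from
    ``smi_params`` or fitted to the supplied reference population (falling
    back to the analysis animals themselves).
    """
    df = metadata.copy()
    if smi_params is None:
        masses = reference_masses if reference_masses is not None else df["mass_g"]
        lengths = reference_lengths if reference_lengths is not None else df["length_mm"]
        smi_params = fit_smi_params(np.asarray(masses), np.asarray(lengths))
    df["smi"] = [
        smi(m, l, smi_params) for m, l in zip(df["mass_g"], df["length_mm"])
    ]
    breaks = size_breaks_by_sex(df["length_mm"], df["sex"])
    df["size_class"] = [
        size_class(l, s, breaks) for l, s in zip(df["length_mm"], df["sex"])
    ]
    df["season"] = [season_from_month(int(m)) for m in df["month"]]
    df["coast_distance"] = [
        river_distance(spatial[str(o)]) for o in df["otter_id"]
    ]
    df["habitat"] = [assign_habitat(spatial[str(o)]) for o in df["otter_id"]]
    return df


def spatial_from_frame(df: pd.DataFrame) -> dict[str, SpatialInputs]:
    """Parse a spatial-inputs CSV (candidate distances semicolon-separated)."""
    out: dict[str, SpatialInputs] = {}
    for row in df.itertuples(index=False):
        raw = str(row.candidate_river_distances)
        cands = tuple(
            float(v) for v in raw.split(";") if v not in ("", "nan")
        )
        out[str(row.otter_id)] = SpatialInputs(
            otter_id=str(row.otter_id),
            candidate_river_distances=cands,
            within_1km_coast=bool(row.within_1km_coast),
            closer_to_coast_than_river=bool(row.closer_to_coast_than_river),
            dist_transitional=float(row.dist_transitional),
            dist_lake=float(row.dist_lake),
            main_channel_length=float(row.main_channel_length),
            tributary_length=float(row.tributary_length),
        )
    return out


def spatial_to_frame(spatial: Mapping[str, SpatialInputs]) -> pd.DataFrame:
    rows = [
        {
            "otter_id": s.otter_id,
            "candidate_river_distances": ";".join(
                str(v) for v in s.candidate_river_distances
            ),
            "within_1km_coast": int(s.within_1km_coast),
            "closer_to_coast_than_river": int(s.closer_to_coast_than_river),
            "dist_transitional": s.dist_transitional,
            "dist_lake": s.dist_lake,
            "main_channel_length": s.main_channel_length,
            "tributary_length": s.tributary_length,
        }
        for s in spatial.values()
    ]
    return pd.DataFrame(rows)
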