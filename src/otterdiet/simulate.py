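"""Synthetic multi-marker diet datasets with known truth.

The generator emulates a fecal metabarcoding study of a semi-aquatic
predator: per-otter true prey sets driven by spatial gradients, two markers
with different taxonomic coverage and resolution (a vertebrate-targeted 16S
assay and an invertebrate-leaning COI assay that calls some vertebrates only
to family or composite level), read tables with log-normal depths plus
Poisson contamination reaching negatives and unused tag combinations, and a
sparser, coarser morphological channel.  Every random draw flows from one
seed through named substreams, and a :class:`TruthRecord` keeps the true
diets and labels every stray-read cell, so recovery and filtering
performance are assertable.

True group presence follows the same complementary log-log model the
analysis fits: ``p = 1 - exp(-exp(alpha_g + beta_lon * lon' +
beta_coast * coast'))`` with covariates standardised by fixed constants
(so effect sizes are per ~1 SD of the configured covariate ranges).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import SpatialInputs, river_distance
from .filtering import ReadTable
from .reconcile import PresenceRecord
from .taxonomy import MorphCategory, TaxonNode, TaxonomyTree, category_index


# -- the reference taxonomy ------------------------------------------------

def _lineage(*rows):
    return [TaxonNode(*r) for r in rows]


def default_taxonomy() -> TaxonomyTree:
    """Small but realistic prey taxonomy: fish clades with genus and species
    ranks below family, amphibians, a bird, the predator itself, crayfish,
    a <3 mm cladoceran, a diatom, and two marine mock-community species."""
    nodes = _lineage(
        ("Animalia", "Animalia", "kingdom", None),
        ("Chordata", "Chordata", "phylum", "Animalia"),
        ("Actinopterygii", "Actinopterygii", "class", "Chordata"),
        ("Salmoniformes", "Salmoniformes", "order", "Actinopterygii"),
        ("Salmonidae", "Salmonidae", "family", "Salmoniformes"),
        ("Salmo", "Salmo", "genus", "Salmonidae"),
        ("Salmo_trutta", "brown trout", "species", "Salmo"),
        ("Anguilliformes", "Anguilliformes", "order", "Actinopterygii"),
        ("Anguillidae", "Anguillidae", "family", "Anguilliformes"),
        ("Anguilla", "Anguilla", "genus", "Anguillidae"),
        ("Anguilla_anguilla", "European eel", "species", "Anguilla"),
        ("Perciformes", "Perciformes", "order", "Actinopterygii"),
        ("Percidae", "Percidae", "family", "Perciformes"),
        ("Perca", "Perca", "genus", "Percidae"),
        ("Perca_fluviatilis", "perch", "species", "Perca"),
        ("Gasterosteiformes", "Gasterosteiformes", "order", "Actinopterygii"),
        ("Gasterosteidae", "Gasterosteidae", "family", "Gasterosteiformes"),
        ("Gasterosteus", "Gasterosteus", "genus", "Gasterosteidae"),
        ("Gasterosteus_aculeatus", "three-spined stickleback", "species", "Gasterosteus"),
        ("Scorpaeniformes", "Scorpaeniformes", "order", "Actinopterygii"),
        ("Cottidae", "Cottidae", "family", "Scorpaeniformes"),
        ("Cottus", "Cottus", "genus", "Cottidae"),
        ("Cottus_gobio", "European bullhead", "species", "Cottus"),
        ("Cypriniformes", "Cypriniformes", "order", "Actinopterygii"),
        ("Cyprinidae", "Cyprinidae", "family", "Cypriniformes"),
        ("Rutilus", "Rutilus", "genus", "Cyprinidae"),
        ("Rutilus_rutilus", "roach", "species", "Rutilus"),
        ("Scardinius", "Scardinius", "genus", "Cyprinidae"),
        ("Scardinius_erythrophthalmus", "rudd", "species", "Scardinius"),
        ("Abramis", "Abramis", "genus", "Cyprinidae"),
        ("Abramis_brama", "common bream", "species", "Abramis"),
        ("Pleuronectiformes", "Pleuronectiformes", "order", "Actinopterygii"),
        ("Pleuronectidae", "Pleuronectidae", "family", "Pleuronectiformes"),
        ("Platichthys", "Platichthys", "genus", "Pleuronectidae"),
        ("Platichthys_flesus", "European flounder", "species", "Platichthys"),
        ("Clupeiformes", "Clupeiformes", "order", "Actinopterygii"),
        ("Clupeidae", "Clupeidae", "family", "Clupeiformes"),
        ("Clupea", "Clupea", "genus", "Clupeidae"),
        ("Clupea_harengus", "Atlantic herring", "species", "Clupea"),
        ("Sprattus", "Sprattus", "genus", "Clupeidae"),
        ("Sprattus_sprattus", "European sprat", "species", "Sprattus"),
        ("Amphibia", "Amphibia", "class", "Chordata"),
        ("Anura", "Anura", "order", "Amphibia"),
        ("Ranidae", "Ranidae", "family", "Anura"),
        ("Rana", "Rana", "genus", "Ranidae"),
        ("Rana_temporaria", "common frog", "species", "Rana"),
        ("Bufonidae", "Bufonidae", "family", "Anura"),
        ("Bufo", "Bufo", "genus", "Bufonidae"),
        ("Bufo_bufo", "common toad", "species", "Bufo"),
        ("Aves", "Aves", "class", "Chordata"),
        ("Gruiformes", "Gruiformes", "order", "Aves"),
        ("Rallidae", "Rallidae", "family", "Gruiformes"),
        ("Gallinula", "Gallinula", "genus", "Rallidae"),
        ("Gallinula_chloropus", "common moorhen", "species", "Gallinula"),
        ("Mammalia", "Mammalia", "class", "Chordata"),
        ("Carnivora", "Carnivora", "order", "Mammalia"),
        ("Mustelidae", "Mustelidae", "family", "Carnivora"),
        ("Lutra", "Lutra", "genus", "Mustelidae"),
        ("Lutra_lutra", "Eurasian otter", "species", "Lutra"),
        ("Arthropoda", "Arthropoda", "phylum", "Animalia"),
        ("Malacostraca", "Malacostraca", "class", "Arthropoda"),
        ("Decapoda", "Decapoda", "order", "Malacostraca"),
        ("Astacidae", "Astacidae", "family", "Decapoda"),
        ("Pacifastacus", "Pacifastacus", "genus", "Astacidae"),
        ("Pacifastacus_leniusculus", "signal crayfish", "species", "Pacifastacus"),
        ("Austropotamobius", "Austropotamobius", "genus", "Astacidae"),
        ("Austropotamobius_pallipes", "white-clawed crayfish", "species", "Austropotamobius"),
        ("Branchiopoda", "Branchiopoda", "class", "Arthropoda"),
        ("Cladocera", "Cladocera", "order", "Branchiopoda"),
        ("Daphniidae", "Daphniidae", "family", "Cladocera"),
        ("Daphnia", "Daphnia", "genus", "Daphniidae"),
        ("Daphnia_pulex", "water flea", "species", "Daphnia"),
        ("Chromista", "Chromista", "kingdom", None),
        ("Bacillariophyta", "Bacillariophyta", "phylum", "Chromista"),
        ("Bacillariophyceae", "Bacillariophyceae", "class", "Bacillariophyta"),
        ("Naviculales", "Naviculales", "order", "Bacillariophyceae"),
        ("Naviculaceae", "Naviculaceae", "family", "Naviculales"),
        ("Navicula", "Navicula", "genus", "Naviculaceae"),
        ("Navicula_sp", "diatom", "species", "Navicula"),
    )
    # infraclass-style coarse label attached at the nearest coarser ladder rank
    nodes.append(TaxonNode("Eutheria", "Eutheria", "order", "Mammalia", off_ladder=True))
    return TaxonomyTree(nodes)


def default_categories() -> dict[str, MorphCategory]:
    return category_index(
        [
            MorphCategory(
                "rudd_roach",
                frozenset({"Rutilus_rutilus", "Scardinius_erythrophthalmus"}),
            )
        ]
    )


#: taxa flagged as maximum body size < 3 mm (secondary/accidental ingestion)
DEFAULT_TRAITS = {"Navicula_sp": True, "Daphnia_pulex": True}

MOCK_TAXA = ("Clupea_harengus", "Sprattus_sprattus")


@dataclass(frozen=True)
class GroupSpec:
    """One prey group: member taxa with draw weights and cloglog effects."""

    taxa: Mapping[str, float]
    alpha: float
    beta_lon: float = 0.0
    beta_coast: float = 0.0


def default_groups() -> dict[str, GroupSpec]:
    """Study-structured defaults.

    Intercepts target true prevalences a little above the observed
    frequencies of occurrence (detection is imperfect); westward prey carry
    negative longitude effects, eastward prey positive; coastal prey carry
    negative coast-distance effects, inland prey positive.
    """
    return {
        "stickleback": GroupSpec({"Gasterosteus_aculeatus": 1.0}, alpha=-0.60),
        "brown_trout": GroupSpec({"Salmo_trutta": 1.0}, alpha=-0.65, beta_lon=-0.6),
        "eel": GroupSpec({"Anguilla_anguilla": 1.0}, alpha=-1.05, beta_coast=-0.7),
        "bullhead": GroupSpec({"Cottus_gobio": 1.0}, alpha=-1.15, beta_coast=0.6),
        "cyprinids": GroupSpec(
            {"Rutilus_rutilus": 0.5, "Scardinius_erythrophthalmus": 0.3,
             "Abramis_brama": 0.2},
            alpha=-1.60, beta_lon=0.6,
        ),
        "percids": GroupSpec({"Perca_fluviatilis": 1.0}, alpha=-2.20, beta_lon=0.5),
        "amphibians": GroupSpec(
            {"Rana_temporaria": 0.7, "Bufo_bufo": 0.3}, alpha=-1.80, beta_lon=-0.5
        ),
        "waterfowl": GroupSpec({"Gallinula_chloropus": 1.0}, alpha=-2.30),
        "crayfish": GroupSpec(
            {"Pacifastacus_leniusculus": 0.7, "Austropotamobius_pallipes": 0.3},
            alpha=-2.10,
        ),
        "marine_fish": GroupSpec(
            {"Platichthys_flesus": 1.0}, alpha=-2.30, beta_lon=-0.4, beta_coast=-0.8
        ),
    }


def default_marker_detection() -> dict[str, dict]:
    # 16S targets vertebrates; COI targets invertebrates but picks up some
    # vertebrates with reduced coverage
    return {
        "16S": {"default_vertebrate": 0.85, "default_invertebrate": 0.10,
                "overrides": {}},
        "COI": {"default_vertebrate": 0.35, "default_invertebrate": 0.85,
                "overrides": {}},
    }


def default_resolution_ceiling() -> dict[str, dict[str, str]]:
    """Marker -> taxon -> emitted label (coarser than the true taxon)."""
    return {
        "16S": {},
        "COI": {
            "Rutilus_rutilus": "rudd_roach",
            "Scardinius_erythrophthalmus": "rudd_roach",
            "Rana_temporaria": "Ranidae",
            "Salmo_trutta": "Salmonidae",
        },
    }


def default_morph_coarsening() -> dict[str, str]:
    return {
        "Salmo_trutta": "Salmo",  # genus-only call, unassignable to a group
        "Rana_temporaria": "Anura",
        "Bufo_bufo": "Anura",
        "Pacifastacus_leniusculus": "Astacidae",
        "Austropotamobius_pallipes": "Astacidae",
        "Gallinula_chloropus": "Rallidae",
        "Platichthys_flesus": "Pleuronectidae",
        "Abramis_brama": "Cyprinidae",  # unassignable coarse cyprinid
        "Perca_fluviatilis": "Percidae",
    }


def default_hard_part_prob() -> dict:
    return {
        "default": 0.30,
        "overrides": {
            "Cottus_gobio": 0.50,
            "Gasterosteus_aculeatus": 0.50,
            "Pacifastacus_leniusculus": 0.55,
            "Austropotamobius_pallipes": 0.55,
            "Anguilla_anguilla": 0.25,
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with study-conditioned defaults."""

    seed: int
    n_otters: int = 300
    groups: dict[str, GroupSpec] = field(default_factory=default_groups)
    marker_detection: dict = field(default_factory=default_marker_detection)
    resolution_ceiling: dict = field(default_factory=default_resolution_ceiling)
    read_depth_logmean: float = 6.5  # exp(6.5) ~ 665 reads per detection
    read_depth_logsd: float = 1.0
    consumer_depth_factor: float = 5.0  # the predator's own DNA dominates
    contamination_rate: float = 0.10  # Poisson mean stray reads per cell
    tag_jump_rate: float = 0.002  # fraction of per-taxon fecal reads per unused tag
    n_extraction_negative: int = 4
    n_pcr_negative: int = 4
    n_unused_tag: int = 4
    n_mock: int = 2
    morph_hard_part: dict = field(default_factory=default_hard_part_prob)
    morph_coarsening: dict = field(default_factory=default_morph_coarsening)
    secondary_injection_rate: float = 0.08  # insect/mollusk/mammal morph records
    bird_coarse_rate: float = 0.3  # chance a morph bird call is just "Aves"
    extra_member_prob: float = 0.15  # second taxon within a present group
    # covariate ranges: a west-east longitude span and river coast distances
    lon_range: tuple[float, float] = (-5.5, 1.0)
    lat_range: tuple[float, float] = (50.5, 54.5)
    coast_max_km: float = 60.0
    lon_center: float = -2.25
    lon_scale: float = 1.9  # ~SD of a uniform over lon_range
    coast_center: float = 25.0
    coast_scale: float = 17.0
    link: str = "cloglog"  # or "logit" for robustness testing

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("contamination_rate", "tag_jump_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("secondary_injection_rate", "extra_member_prob",
                     "bird_coarse_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.link not in ("cloglog", "logit"):
            raise ValueError(f"unknown link {self.link!r}")

    def hash(self) -> str:
        payload = asdict(self)
        payload["groups"] = {
            k: asdict(v) for k, v in sorted(self.groups.items())
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def substream(self, name: str) -> np.random.Generator:
        """Named, order-independent substream derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return np.random.default_rng(
            np.random.SeedSequence(int.from_bytes(digest[:8], "little"))
        )


@dataclass
class TruthRecord:
    """Ground truth for one generated dataset."""

    diets: dict[str, set[str]]  # otter -> true prey taxa
    group_presence: dict[str, set[str]]  # otter -> true prey groups
    detections: dict[str, dict[str, set[str]]]  # channel -> otter -> labels
    contamination: dict[str, list[tuple[str, str]]]  # marker -> stray cells
    config_hash: str


# -- stage 1: the world ----------------------------------------------------

def generate_world(
    cfg: GeneratorConfig,
) -> tuple[TaxonomyTree, dict[str, MorphCategory], pd.DataFrame, dict[str, SpatialInputs]]:
    """Taxonomy, otter metadata and precomputed spatial inputs."""
    tree = default_taxonomy()
    categories = default_categories()
    rng = cfg.substream("world")
    n = cfg.n_otters
    ids = [f"OTT{i:04d}" for i in range(n)]
    sex = rng.choice(["M", "F"], size=n)
    length = np.where(
        sex == "M", rng.normal(1090.0, 60.0, n), rng.normal(980.0, 55.0, n)
    )
    length = np.round(np.clip(length, 800.0, 1350.0) / 5) * 5  # to nearest 5 mm
    # allometric mass with multiplicative noise
    log_c = np.log(8000.0) - 2.7 * np.log(1090.0)
    mass = np.exp(log_c + 2.7 * np.log(length) + rng.normal(0.0, 0.12, n))
    metadata = pd.DataFrame(
        {
            "otter_id": ids,
            "sex": sex,
            "length_mm": length,
            "mass_g": np.round(mass, 1),
            "year": rng.integers(2007, 2017, n),
            "month": rng.integers(1, 13, n),
            "lat": np.round(rng.uniform(*cfg.lat_range, n), 4),
            "lon": np.round(rng.uniform(*cfg.lon_range, n), 4),
            "pct_urban": np.round(rng.beta(2.0, 8.0, n), 4),
        }
    )
    spatial: dict[str, SpatialInputs] = {}
    for i, oid in enumerate(ids):
        coastal = rng.random() < 0.08
        d_true = float(rng.uniform(0.0, cfg.coast_max_km))
        k = int(rng.integers(1, 4))
        cands = tuple(
            float(max(0.0, d_true + rng.normal(0.0, 0.5))) for _ in range(k)
        )
        spatial[oid] = SpatialInputs(
            otter_id=oid,
            candidate_river_distances=cands,
            within_1km_coast=coastal,
            closer_to_coast_than_river=coastal,
            dist_transitional=float(rng.uniform(0.5, 40.0))
            if rng.random() < 0.08 else float(rng.uniform(5.0, 80.0)),
            dist_lake=float(rng.uniform(0.5, 40.0))
            if rng.random() < 0.12 else float(rng.uniform(5.0, 80.0)),
            main_channel_length=float(rng.lognormal(1.5, 0.8)),
            tributary_length=float(rng.lognormal(2.5, 0.8)),
        )
    return tree, categories, metadata, spatial


# -- stage 2: true diets ---------------------------------------------------

def _presence_prob(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "cloglog":
        return -np.expm1(-np.exp(np.clip(eta, -30, 3.2)))
    return 1.0 / (1.0 + np.exp(-eta))


def generate_true_diets(
    metadata: pd.DataFrame,
    spatial: Mapping[str, SpatialInputs],
    cfg: GeneratorConfig,
) -> TruthRecord:
    """Per-otter prey groups from the spatial model, then member taxa."""
    rng = cfg.substream("diets")
    lon_std = (metadata["lon"].to_numpy() - cfg.lon_center) / cfg.lon_scale
    coast = np.array(
        [river_distance(spatial[str(o)]) for o in metadata["otter_id"]]
    )
    coast_std = (coast - cfg.coast_center) / cfg.coast_scale
    diets: dict[str, set[str]] = {}
    group_presence: dict[str, set[str]] = {}
    for i, oid in enumerate(metadata["otter_id"]):
        oid = str(oid)
        diets[oid] = set()
        group_presence[oid] = set()
        for gname, spec in cfg.groups.items():
            eta = spec.alpha + spec.beta_lon * lon_std[i] + spec.beta_coast * coast_std[i]
            p = _presence_prob(np.array(eta), cfg.link)
            if rng.random() < p:
                group_presence[oid].add(gname)
                members = list(spec.taxa)
                weights = np.array([spec.taxa[t] for t in members], dtype=float)
                weights /= weights.sum()
                primary = members[int(rng.choice(len(members), p=weights))]
                diets[oid].add(primary)
                for t in members:
                    if t != primary and rng.random() < cfg.extra_member_prob:
                        diets[oid].add(t)
    return TruthRecord(
        diets=diets,
        group_presence=group_presence,
        detections={},
        contamination={},
        config_hash=cfg.hash(),
    )


# -- stage 3: marker read tables -------------------------------------------

def _detection_prob(cfg: GeneratorConfig, marker: str, taxon: str,
                    tree: TaxonomyTree) -> float:
    md = cfg.marker_detection[marker]
    if taxon in md["overrides"]:
        return float(md["overrides"][taxon])
    is_vert = "Chordata" in tree.root_path(taxon)
    return float(md["default_vertebrate"] if is_vert else md["default_invertebrate"])


def generate_reads(
    truth: TruthRecord,
    metadata: pd.DataFrame,
    tree: TaxonomyTree,
    cfg: GeneratorConfig,
    marker: str,
) -> ReadTable:
    """One marker's sample x taxon count table, controls included.

    True detections get log-normal read depths at the marker's emitted
    resolution; the consumer's own DNA dominates every fecal sample;
    Poisson contamination hits random cells in all samples, and unused tag
    combinations receive donor-proportional tag-jump counts.  Stray cells
    that are not true detections are recorded in ``truth.contamination``.
    """
    rng = cfg.substream(f"reads:{marker}")
    ceiling = cfg.resolution_ceiling.get(marker, {})
    prey_taxa = sorted({t for d in truth.diets.values() for t in d})
    emitted = sorted(
        {ceiling.get(t, t) for t in prey_taxa}
        | {"Lutra_lutra", "Navicula_sp"}
        | set(MOCK_TAXA)
    )
    fecal_ids = [str(o) for o in metadata["otter_id"]]
    control_ids = (
        [f"NEGX{i}" for i in range(cfg.n_extraction_negative)]
        + [f"NEGP{i}" for i in range(cfg.n_pcr_negative)]
        + [f"UNUSED{i}" for i in range(cfg.n_unused_tag)]
        + [f"MOCK{i}" for i in range(cfg.n_mock)]
    )
    roles = pd.Series(
        ["fecal"] * len(fecal_ids)
        + ["extraction_negative"] * cfg.n_extraction_negative
        + ["pcr_negative"] * cfg.n_pcr_negative
        + ["unused_tag"] * cfg.n_unused_tag
        + ["mock"] * cfg.n_mock,
        index=fecal_ids + control_ids,
    )
    counts = pd.DataFrame(
        0, index=fecal_ids + control_ids, columns=emitted, dtype=np.int64
    )

    def depth() -> int:
        return max(1, int(round(rng.lognormal(cfg.read_depth_logmean,
                                              cfg.read_depth_logsd))))

    detections: dict[str, set[str]] = {}
    for oid in fecal_ids:
        detected: set[str] = set()
        for taxon in sorted(truth.diets[oid]):
            if rng.random() < _detection_prob(cfg, marker, taxon, tree):
                label = ceiling.get(taxon, taxon)
                counts.loc[oid, label] += depth()
                detected.add(label)
        # the consumer's own DNA and incidental environmental diatoms
        counts.loc[oid, "Lutra_lutra"] += int(cfg.consumer_depth_factor * depth())
        if rng.random() < 0.10:
            counts.loc[oid, "Navicula_sp"] += depth()
            detected.add("Navicula_sp")
        detected.add("Lutra_lutra")
        detections[oid] = detected
    # mock communities: standardised marine mixtures
    for sid in control_ids:
        if roles[sid] == "mock":
            for t in MOCK_TAXA:
                counts.loc[sid, t] = 5000

    contamination: list[tuple[str, str]] = []
    if cfg.contamination_rate > 0:
        stray = rng.poisson(cfg.contamination_rate, size=counts.shape)
        for i, sid in enumerate(counts.index):
            for j, label in enumerate(emitted):
                if stray[i, j] > 0:
                    counts.iloc[i, j] += int(stray[i, j])
                    if roles[sid] != "fecal" or label not in detections.get(sid, set()):
                        contamination.append((sid, label))
    if cfg.tag_jump_rate > 0:
        fecal_mean = counts.loc[fecal_ids].mean(axis=0).to_numpy()
        for sid in control_ids:
            if roles[sid] != "unused_tag":
                continue
            jumps = rng.poisson(cfg.tag_jump_rate * fecal_mean)
            for j, label in enumerate(emitted):
                if jumps[j] > 0:
                    counts.loc[sid, label] += int(jumps[j])
                    contamination.append((sid, label))

    truth.detections[f"marker{marker}"] = detections
    truth.contamination[marker] = contamination
    return ReadTable(marker, counts, roles)


# -- stage 4: morphology ---------------------------------------------------

def generate_morphology(
    truth: TruthRecord,
    metadata: pd.DataFrame,
    cfg: GeneratorConfig,
) -> list[PresenceRecord]:
    """Sparse, coarse hard-part detections, plus secondary-prey injections."""
    rng = cfg.substream("morph")
    hp = cfg.morph_hard_part
    records: list[PresenceRecord] = []
    detections: dict[str, set[str]] = {}
    for oid in (str(o) for o in metadata["otter_id"]):
        labels: set[str] = set()
        for taxon in sorted(truth.diets[oid]):
            p = hp["overrides"].get(taxon, hp["default"])
            if rng.random() < p:
                label = cfg.morph_coarsening.get(taxon, taxon)
                if label == "Rallidae" and rng.random() < cfg.bird_coarse_rate:
                    label = "Aves"  # feather only, unidentifiable further
                labels.add(label)
        if rng.random() < cfg.secondary_injection_rate:
            labels.add(str(rng.choice(["insect", "mollusk", "snail", "mammal"])))
        for label in sorted(labels):
            records.append(PresenceRecord(oid, label, "morphology"))
        detections[oid] = labels
    truth.detections["morphology"] = detections
    return records


# -- all together ----------------------------------------------------------

def default_group_map() -> tuple[dict[str, str], frozenset[str]]:
    """taxon/label -> prey group for every label the channels can emit,
    plus the labels too coarse to assign (dropped at grouping)."""
    mapping = {
        "Gasterosteus_aculeatus": "stickleback",
        "Salmo_trutta": "brown_trout",
        "Salmonidae": "brown_trout",
        "Anguilla_anguilla": "eel",
        "Cottus_gobio": "bullhead",
        "Rutilus_rutilus": "cyprinids",
        "Scardinius_erythrophthalmus": "cyprinids",
        "Abramis_brama": "cyprinids",
        "rudd_roach": "cyprinids",
        "Perca_fluviatilis": "percids",
        "Percidae": "percids",
        "Rana_temporaria": "amphibians",
        "Bufo_bufo": "amphibians",
        "Ranidae": "amphibians",
        "Anura": "amphibians",
        "Gallinula_chloropus": "waterfowl",
        "Rallidae": "waterfowl",
        "Pacifastacus_leniusculus": "crayfish",
        "Austropotamobius_pallipes": "crayfish",
        "Astacidae": "crayfish",
        "Platichthys_flesus": "marine_fish",
        "Pleuronectidae": "marine_fish",
    }
    unassigned = frozenset(
        {"Salmo", "Cyprinidae", "Aves", "Clupea_harengus", "Sprattus_sprattus"}
    )
    return mapping, unassigned


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: GeneratorConfig
    tree: TaxonomyTree
    categories: dict[str, MorphCategory]
    metadata: pd.DataFrame
    spatial: dict[str, SpatialInputs]
    truth: TruthRecord
    reads: dict[str, ReadTable]
    morphology: list[PresenceRecord]
    traits: dict[str, bool]
    group_map: dict[str, str]
    unassigned: frozenset[str]


def simulate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Run all generator stages under the configured seed."""
    tree, categories, metadata, spatial = generate_world(cfg)
    truth = generate_true_diets(metadata, spatial, cfg)
    reads = {
        marker: generate_reads(truth, metadata, tree, cfg, marker)
        for marker in ("16S", "COI")
    }
    morphology = generate_morphology(truth, metadata, cfg)
    mapping, unassigned = default_group_map()
    traits = {tid: False for tid in tree.ids}
    traits.update({label: False for label in categories})
    traits.update(DEFAULT_TRAITS)
    return SyntheticDataset(
        config=cfg,
        tree=tree,
        categories=categories,
        metadata=metadata,
        spatial=spatial,
        truth=truth,
        reads=reads,
        morphology=morphology,
        traits=traits,
        group_map=mapping,
        unassigned=unassigned,
    )
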