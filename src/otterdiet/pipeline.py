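"""End-to-end orchestration: simulate/load -> filter -> reconcile -> group -> model.

Each stage is also callable on its own (see the per-stage modules); this
module chains them under a single YAML-able config, collects a run manifest
(config hash, per-stage record counts, removal tallies, partition
statistics, versions) and fails fast with stage-named errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .covariates import build_covariates, spatial_from_frame
from .diet import (
    PreyGroupMap, drop_rare_groups, frequency_of_occurrence, map_to_groups,
    mean_taxa_per_sample,
)
from .filtering import (
    FilterConfig, ReadTable, filter_table, read_table_tsv, remove_nonfood,
    to_presence,
)
from .mglm import DietCompositionModel, stepwise_aic
from .reconcile import (
    PresenceRecord, combine_methods, merge_marker_presences, partition_stats,
    records_from_frame, records_from_matrix, remove_secondary,
)
from .simulate import GeneratorConfig, simulate
from .taxonomy import read_categories, read_taxonomy

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "n_otters": 300,
    "inputs": {},  # file paths when simulate is false
    "filter": {"proportional_thresholds": {"16S": 0.005, "COI": 0.003}},
    "coarse_blocklist": ["Eutheria"],
    "consumer_taxon": "Lutra_lutra",
    "min_group_samples": 3,
    "terms": ["lon", "coast_distance"],
    "stepwise": False,
    "candidate_terms": None,
    "n_resamples": 199,
}


def make_config(overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    outputs: dict = field(default_factory=dict)

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest, sort_keys=True, default=str).encode()
        ).hexdigest()


def matrix_from_records(records: list[PresenceRecord]) -> pd.DataFrame:
    """Binary sample x taxon matrix from long-form records."""
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(
        [(r.sample_id, r.taxon) for r in records], columns=["sample_id", "taxon"]
    )
    m = pd.crosstab(df["sample_id"], df["taxon"]).clip(upper=1)
    return m.astype(np.int64)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load_inputs(cfg: dict):
    paths = cfg["inputs"]
    tree = read_taxonomy(paths["taxonomy"])
    categories = read_categories(paths["categories"]) if paths.get("categories") else {}
    reads = {
        "16S": read_table_tsv(paths["reads_16s"], "16S"),
        "COI": read_table_tsv(paths["reads_coi"], "COI"),
    }
    morphology = records_from_frame(
        pd.read_csv(paths["morphology"]), channel="morphology"
    )
    metadata = pd.read_csv(paths["metadata"])
    spatial = spatial_from_frame(pd.read_csv(paths["spatial"]))
    gm = pd.read_csv(paths["group_map"], sep="\t")
    traits_df = pd.read_csv(paths["traits"], sep="\t")
    traits = dict(
        zip(traits_df["taxon_id"].astype(str), traits_df["small_body"].astype(bool))
    )
    unassigned = frozenset(
        pd.read_csv(paths["unassigned"], sep="\t")["taxon_id"].astype(str)
    ) if paths.get("unassigned") else frozenset()
    mapping = dict(zip(gm["taxon_id"].astype(str), gm["group"].astype(str)))
    return tree, categories, reads, morphology, metadata, spatial, mapping, unassigned, traits


def run_all(
    config: dict | None = None,
    generator_config: GeneratorConfig | None = None,
) -> PipelineResult:
    """Execute the full pipeline and return outputs plus a run manifest.

    A pre-built :class:`GeneratorConfig` overrides the config's
    ``seed``/``n_otters`` pair when simulating, allowing custom prey pools
    and effect sizes to flow through the whole pipeline.
    """
    cfg = make_config(config)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {
            "otterdiet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    outputs: dict[str, Any] = {}

    if cfg["simulate"]:
        try:
            gen_cfg = generator_config or GeneratorConfig(
                seed=int(cfg["seed"]), n_otters=int(cfg["n_otters"])
            )
            ds = simulate(gen_cfg)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate': {exc}") from exc
        tree, categories = ds.tree, ds.categories
        reads, morphology = ds.reads, ds.morphology
        metadata, spatial = ds.metadata, ds.spatial
        mapping, unassigned, traits = ds.group_map, ds.unassigned, ds.traits
        outputs["dataset"] = ds
        manifest["generator_config_hash"] = ds.config.hash()
    else:
        (tree, categories, reads, morphology, metadata, spatial,
         mapping, unassigned, traits) = _load_inputs(cfg)

    fc = FilterConfig(
        proportional_thresholds=cfg["filter"]["proportional_thresholds"],
        consumer_taxon=cfg["consumer_taxon"],
        coarse_blocklist=frozenset(cfg["coarse_blocklist"]),
    )

    # per-marker filtering -> presence records -> nonfood removal
    marker_records: dict[str, list[PresenceRecord]] = {}
    for marker, table in reads.items():
        try:
            filtered = filter_table(table, fc)
            presence = to_presence(filtered)
            raw_presence = to_presence(table)
            recs = records_from_matrix(presence, channel=f"marker{marker}")
            kept, tallies = remove_nonfood(recs, tree, fc, traits, categories)
            marker_records[marker] = kept
            manifest["stages"][f"filter_{marker}"] = {
                "raw_presences": int(raw_presence.to_numpy().sum()),
                "filtered_presences": int(presence.to_numpy().sum()),
                "after_nonfood": len(kept),
                "nonfood_tallies": tallies,
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'filter:{marker}': {exc}") from exc

    try:
        dna = merge_marker_presences(
            marker_records["16S"], marker_records["COI"], tree, categories
        )
        marker_partition = partition_stats(
            marker_records["16S"], marker_records["COI"], tree, categories
        )
        manifest["stages"]["merge_markers"] = {
            "records": len(dna), "partition": marker_partition,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'merge_markers': {exc}") from exc

    try:
        morph_kept = remove_secondary(morphology)
        combined = combine_methods(dna, morph_kept, tree, categories)
        method_partition = partition_stats(
            dna, morph_kept, tree, categories, collapse_partial=True
        )
        manifest["stages"]["combine_methods"] = {
            "morph_records_in": len(list(morphology)),
            "morph_after_secondary": len(morph_kept),
            "combined_records": len(combined),
            "partition": method_partition,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'combine_methods': {exc}") from exc

    try:
        taxa_matrix = matrix_from_records(combined)
        groups = map_to_groups(taxa_matrix, PreyGroupMap(mapping, unassigned))
        groups = drop_rare_groups(groups, cfg["min_group_samples"])
        groups = groups.loc[groups.sum(axis=1) > 0]
        manifest["stages"]["grouping"] = {
            "samples_with_data": int(len(groups)),
            "groups": list(map(str, groups.columns)),
            "total_presences": int(groups.to_numpy().sum()),
            "mean_groups_per_sample": round(mean_taxa_per_sample(groups), 2),
        }
        outputs["group_matrix"] = groups
        outputs["fo_table"] = frequency_of_occurrence(groups).sort_values(
            ascending=False
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'grouping': {exc}") from exc

    try:
        covs = build_covariates(metadata, spatial)
        covs = covs.set_index("otter_id")
        covs = covs.loc[[o for o in groups.index if o in covs.index]]
        response = groups.loc[covs.index]
        manifest["stages"]["covariates"] = {"rows": int(len(covs))}
        outputs["covariates"] = covs
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'covariates': {exc}") from exc

    try:
        terms = list(cfg["terms"])
        if cfg["stepwise"]:
            candidates = cfg["candidate_terms"] or terms
            terms = stepwise_aic(response, covs, candidates)
        model = DietCompositionModel(response, covs, terms)
        results = model.fit()
        anova = results.anova(
            n_resamples=int(cfg["n_resamples"]), seed=int(cfg["seed"])
        )
        manifest["stages"]["mglm"] = {
            "terms": terms,
            "n_resamples": int(cfg["n_resamples"]),
            "dropped_rows": model.n_dropped,
            "community_deviance": round(results.community_deviance, 4),
            "anova": [
                {
                    "term": row.term,
                    "deviance": round(float(row.deviance), 4),
                    "p_value": round(float(row.p_value), 6),
                }
                for row in anova.table.itertuples(index=False)
            ],
        }
        outputs["results"] = results
        outputs["anova"] = anova
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'mglm': {exc}") from exc

    return PipelineResult(manifest=manifest, outputs=outputs)
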