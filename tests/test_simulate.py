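import numpy as np
import pandas as pd
import pytest

from otterdiet.filtering import to_presence
from otterdiet.reconcile import combine_methods
from otterdiet.simulate import (
    GeneratorConfig, GroupSpec, generate_morphology,
    generate_reads, generate_true_diets, generate_world, simulate,
)


def small_cfg(**kw) -> GeneratorConfig:
    base = dict(seed=1, n_otters=40)
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateWorld:
    def test_same_seed_identical_outputs(self):
        cfg = small_cfg()
        _, _, meta1, spat1 = generate_world(cfg)
        _, _, meta2, spat2 = generate_world(cfg)
        pd.testing.assert_frame_equal(meta1, meta2)
        assert spat1 == spat2

    def test_zero_otters_valid_empty_tables(self):
        _, _, meta, spat = generate_world(small_cfg(n_otters=0))
        assert len(meta) == 0
        assert list(meta.columns)[:3] == ["otter_id", "sex", "length_mm"]
        assert spat == {}

    def test_fish_clades_have_genus_and_species_below_family(self):
        tree, _, _, _ = generate_world(small_cfg())
        ranks = {tree.node(t).rank for t in tree.subtree("Salmonidae")}
        assert {"family", "genus", "species"} <= ranks

    def test_covariate_means_within_three_se(self):
        cfg = GeneratorConfig(seed=3, n_otters=1000)
        _, _, meta, _ = generate_world(cfg)
        lo, hi = cfg.lon_range
        mean, se = (lo + hi) / 2, (hi - lo) / np.sqrt(12) / np.sqrt(1000)
        assert abs(meta["lon"].mean() - mean) < 3 * se

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(contamination_rate=-0.1)
        with pytest.raises(ValueError):
            small_cfg(secondary_injection_rate=1.5)


class TestGenerateTrueDiets:
    def test_null_prevalence_within_binomial_ci(self):
        # with all effects zero the empirical group prevalence must sit in
        # the 99% binomial interval around 1 - exp(-exp(alpha))
        alpha = -1.0
        groups = {"only": GroupSpec({"Cottus_gobio": 1.0}, alpha=alpha)}
        cfg = GeneratorConfig(seed=5, n_otters=2000, groups=groups)
        _, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        p = -np.expm1(-np.exp(alpha))
        n_hit = sum("only" in g for g in truth.group_presence.values())
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(n_hit / 2000 - p) < 2.58 * se * 1.3  # modest slack on 99%

    def test_longitude_gradient_monotone_across_quintiles(self):
        groups = {"west": GroupSpec({"Salmo_trutta": 1.0}, alpha=-1.0,
                                    beta_lon=-2.0)}
        cfg = GeneratorConfig(seed=6, n_otters=2000, groups=groups)
        _, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        present = meta["otter_id"].map(
            lambda o: "west" in truth.group_presence[str(o)]
        ).astype(float)
        bins = pd.qcut(meta["lon"], 5, labels=False)
        means = present.groupby(bins).mean()
        assert (np.diff(means.to_numpy()) < 0).all()

    def test_huge_negative_intercept_never_present(self):
        groups = {"ghost": GroupSpec({"Salmo_trutta": 1.0}, alpha=-20.0)}
        cfg = GeneratorConfig(seed=7, n_otters=500, groups=groups)
        _, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        assert all(len(g) == 0 for g in truth.group_presence.values())


class TestGenerateReads:
    def test_zero_contamination_gives_clean_negatives(self):
        cfg = small_cfg(contamination_rate=0.0, tag_jump_rate=0.0)
        _, _, meta, spat = generate_world(cfg)
        tree, _, _, _ = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        table = generate_reads(truth, meta, tree, cfg, "16S")
        negs = table.samples_with_role(
            "extraction_negative", "pcr_negative", "unused_tag"
        )
        assert (table.counts.loc[negs].to_numpy() == 0).all()
        assert truth.contamination["16S"] == []

    def test_lossless_channel_recovers_truth_exactly(self):
        # detection probability one, no contamination, no resolution ceiling
        md = {
            "16S": {"default_vertebrate": 1.0, "default_invertebrate": 1.0,
                    "overrides": {}},
            "COI": {"default_vertebrate": 1.0, "default_invertebrate": 1.0,
                    "overrides": {}},
        }
        cfg = small_cfg(contamination_rate=0.0, tag_jump_rate=0.0,
                        marker_detection=md,
                        resolution_ceiling={"16S": {}, "COI": {}})
        tree, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        table = generate_reads(truth, meta, tree, cfg, "16S")
        presence = to_presence(table)
        for oid in presence.index:
            support = {t for t, v in presence.loc[oid].items() if v}
            support -= {"Lutra_lutra", "Navicula_sp"}  # predator + incidental
            assert support == truth.diets[str(oid)]

    def test_detection_frequency_within_binomial_ci(self):
        prob = 0.6
        md = {
            "16S": {"default_vertebrate": prob, "default_invertebrate": prob,
                    "overrides": {}},
            "COI": {"default_vertebrate": prob, "default_invertebrate": prob,
                    "overrides": {}},
        }
        groups = {"only": GroupSpec({"Cottus_gobio": 1.0}, alpha=2.0)}
        cfg = GeneratorConfig(seed=9, n_otters=1000, groups=groups,
                              marker_detection=md, contamination_rate=0.0,
                              tag_jump_rate=0.0)
        tree, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        table = generate_reads(truth, meta, tree, cfg, "16S")
        presence = to_presence(table)
        carriers = [o for o, d in truth.diets.items() if "Cottus_gobio" in d]
        hits = presence.loc[carriers, "Cottus_gobio"].mean()
        se = np.sqrt(prob * (1 - prob) / len(carriers))
        assert abs(hits - prob) < 2.58 * se * 1.3

    def test_detections_subset_of_truth_when_clean(self):
        cfg = small_cfg(contamination_rate=0.0, tag_jump_rate=0.0)
        tree, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        generate_reads(truth, meta, tree, cfg, "COI")
        ceiling = cfg.resolution_ceiling["COI"]
        for oid, labels in truth.detections["markerCOI"].items():
            allowed = {ceiling.get(t, t) for t in truth.diets[oid]}
            allowed |= {"Lutra_lutra", "Navicula_sp"}
            assert labels <= allowed


class TestGenerateMorphology:
    def test_zero_hard_part_probability_gives_nothing(self):
        cfg = small_cfg(
            morph_hard_part={"default": 0.0, "overrides": {}},
            secondary_injection_rate=0.0,
        )
        _, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        assert generate_morphology(truth, meta, cfg) == []

    def test_identity_coarsening_full_probability_equals_truth(self):
        cfg = small_cfg(
            morph_hard_part={"default": 1.0, "overrides": {}},
            morph_coarsening={}, secondary_injection_rate=0.0,
        )
        _, _, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        recs = generate_morphology(truth, meta, cfg)
        by_otter: dict[str, set] = {}
        for r in recs:
            by_otter.setdefault(r.sample_id, set()).add(r.taxon)
        for oid, diet in truth.diets.items():
            assert by_otter.get(oid, set()) == diet

    def test_combining_with_dna_never_coarsens_morph_resolution(self):
        # reconciliation gain: every combined record is at least as deep in
        # the taxonomy as the morphological record it matches
        cfg = small_cfg(seed=21)
        tree, cats, meta, spat = generate_world(cfg)
        truth = generate_true_diets(meta, spat, cfg)
        table = generate_reads(truth, meta, tree, cfg, "16S")
        morph = [r for r in generate_morphology(truth, meta, cfg)
                 if r.taxon in tree or r.taxon in cats]
        from otterdiet.reconcile import records_from_matrix

        dna = records_from_matrix(to_presence(table), "marker16S")
        dna = [r for r in dna if r.taxon != "Lutra_lutra"]
        combined = combine_methods(dna, morph, tree, cats)
        depth = {}
        for r in combined:
            if r.taxon in tree:
                depth[(r.sample_id, r.taxon)] = len(tree.root_path(r.taxon))
        for m in morph:
            if m.taxon not in tree:
                continue
            matches = [
                d for (sid, t), d in depth.items()
                if sid == m.sample_id
                and (t == m.taxon or m.taxon in tree.root_path(t))
            ]
            if matches:
                assert max(matches) >= len(tree.root_path(m.taxon))


def test_filtering_removes_most_labelled_contamination():
    """At default thresholds the two filters remove at least 95% of the
    stray-read presences the generator injected into fecal samples."""
    from otterdiet.filtering import FilterConfig, filter_table

    total, surviving = 0, 0
    for seed in (101, 102):
        ds = simulate(GeneratorConfig(seed=seed, n_otters=200))
        for marker, table in ds.reads.items():
            filtered = to_presence(filter_table(table, FilterConfig()))
            detected = ds.truth.detections[f"marker{marker}"]
            for sid, label in ds.truth.contamination[marker]:
                if table.roles[sid] != "fecal":
                    continue
                if label in detected.get(sid, set()):
                    continue  # stray reads stacked on a real detection
                total += 1
                surviving += int(filtered.loc[sid, label] > 0)
    assert total > 100  # the check is only meaningful with real injections
    assert 1 - surviving / total >= 0.95


class TestSimulateEndToEnd:
    def test_deterministic_under_seed(self):
        ds1 = simulate(small_cfg())
        ds2 = simulate(small_cfg())
        pd.testing.assert_frame_equal(ds1.metadata, ds2.metadata)
        for marker in ("16S", "COI"):
            pd.testing.assert_frame_equal(
                ds1.reads[marker].counts, ds2.reads[marker].counts
            )
        assert ds1.morphology == ds2.morphology
        assert ds1.truth.config_hash == ds2.truth.config_hash

    def test_config_hash_sensitive_to_parameters(self):
        assert small_cfg().hash() != small_cfg(contamination_rate=0.2).hash()

    def test_truth_detections_recorded_per_channel(self):
        ds = simulate(small_cfg())
        assert set(ds.truth.detections) == {
            "marker16S", "markerCOI", "morphology"
        }

    def test_group_map_covers_all_emittable_labels(self):
        ds = simulate(small_cfg())
        coverable = set(ds.group_map) | set(ds.unassigned)
        for marker, table in ds.reads.items():
            for label in table.counts.columns:
                if label in ("Lutra_lutra", "Navicula_sp"):
                    continue  # removed as nonfood upstream of grouping
                assert label in coverable
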