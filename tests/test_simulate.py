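"""Synthetic generator: determinism, degenerate profiles, parameter recovery."""

from __future__ import annotations

import numpy as np
import pytest

from taxid_eval import metrics
from taxid_eval.consistency import consistency_results
from taxid_eval.datamodel import ConfigError, MatchCategory
from taxid_eval.scoring import score_records, scores_frame
from taxid_eval.simulate import (
    APP_SUMMARY,
    SimConfig,
    ToolProfile,
    default_profiles,
    generate_taxonomy,
    profile_from_summary,
    recover_profile,
    simulate_records,
    uniform_profiles,
)

C = MatchCategory


def one_tool(probs, rho=0.0, law=None, tool_id="tool1"):
    return ToolProfile(tool_id, probs, law or {1: 1.0}, rho)


class TestConfigAndTaxonomy:
    def test_species_count_is_the_product_of_sizes(self):
        config = SimConfig(n_families=3, n_genera_per_family=2, n_species_per_genus=2,
                           n_samples=3, plant_part_counts={"flower": 3},
                           plant_type_counts={"herb": 3})
        taxonomy, metadata = generate_taxonomy(config)
        assert len(taxonomy) == 12
        assert len(metadata) == 3

    def test_same_seed_reproduces_bit_for_bit(self):
        config = SimConfig(seed=11)
        out1 = generate_taxonomy(config)
        out2 = generate_taxonomy(config)
        assert out1 == out2
        records1 = simulate_records(default_profiles(), out1[1], out1[0], config)
        records2 = simulate_records(default_profiles(), out2[1], out2[0], config)
        assert records1 == records2

    def test_too_small_taxonomy_is_a_config_error(self):
        with pytest.raises(ConfigError):
            SimConfig(n_families=2, n_genera_per_family=1, n_species_per_genus=1,
                      n_samples=5, plant_part_counts={"flower": 5},
                      plant_type_counts={"herb": 5})

    def test_partitions_must_sum_to_sample_count(self):
        with pytest.raises(ConfigError):
            SimConfig(plant_part_counts={"flower": 10, "fruit": 3, "leaf": 10, "plant": 13})

    def test_default_design_mirrors_the_benchmark(self):
        config = SimConfig()
        taxonomy, metadata = generate_taxonomy(config)
        assert len(metadata) == 38 and config.n_replicates == 5
        references = {m.reference.species_name for m in metadata.values()}
        assert len(references) == 38
        assert all(m.reference.species_name in taxonomy for m in metadata.values())

    def test_adding_a_tool_leaves_existing_records_unchanged(self):
        config = SimConfig(seed=2)
        taxonomy, metadata = generate_taxonomy(config)
        profiles = default_profiles()
        base = simulate_records(profiles[:3], metadata, taxonomy, config)
        extended = simulate_records(profiles[:4], metadata, taxonomy, config)
        assert extended[: len(base)] == base


class TestDegenerateProfiles:
    def test_always_correct_profile_scores_100_and_c4(self, ):
        config = SimConfig(seed=3)
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.SPECIES_CORRECT: 1.0})
        records = simulate_records([profile], metadata, taxonomy, config)
        frame = scores_frame(score_records(records))
        assert (frame["first_choice"] == 100).all()
        for res in consistency_results(records, taxonomy, metadata):
            assert res.consistency_C == 4.0

    def test_rho_one_repeats_replicates_verbatim(self):
        config = SimConfig(seed=4)
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.SPECIES_CORRECT: 0.4, C.UNKNOWN: 0.3, C.MISLEADING: 0.3},
                           rho=1.0, law={1: 0.5, 2: 0.5})
        records = simulate_records([profile], metadata, taxonomy, config)
        by_sample = {}
        for rec in records:
            by_sample.setdefault(rec.sample_id, []).append(rec.suggestions)
        for runs in by_sample.values():
            assert all(r == runs[0] for r in runs)

    def test_category_realizations_respect_the_taxonomy(self):
        config = SimConfig(seed=5)
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.GENUS_CORRECT: 0.5, C.FAMILY_CORRECT: 0.25, C.MISLEADING: 0.25})
        records = simulate_records([profile], metadata, taxonomy, config)
        for rec in records:
            ref = metadata[rec.sample_id].reference
            sug = rec.suggestions[0]
            taxon = taxonomy[sug.suggested_name]
            if sug.category is C.GENUS_CORRECT:
                assert taxon.genus == ref.genus
            elif sug.category is C.FAMILY_CORRECT:
                assert taxon.family == ref.family and taxon.genus != ref.genus
            else:
                assert taxon.family != ref.family


class TestMonteCarloCalibration:
    def test_accuracy_band_converges_to_profile_mass(self):
        """With P(first choice >= 80-grade) = 0.6, %>=80 averages 60."""
        probs = {C.SPECIES_CORRECT: 0.3, C.GENUS_CORRECT: 0.3, C.UNKNOWN: 0.4}
        values = []
        for run in range(200):
            config = SimConfig(seed=1000 + run)
            taxonomy, metadata = generate_taxonomy(config)
            records = simulate_records([one_tool(probs)], metadata, taxonomy, config)
            frame = scores_frame(score_records(records))
            values.append(metrics.accuracy_thresholds(frame).iloc[0]["pct_ge_80"])
        n_obs = 200 * 38 * 5
        se = 100 * np.sqrt(0.6 * 0.4 / n_obs)
        assert abs(np.mean(values) - 60.0) < 3 * se


class TestProfileRecovery:
    def test_multinomial_recovered_within_three_se(self):
        p_true = 0.5
        config = SimConfig(n_families=100, n_genera_per_family=10, n_species_per_genus=5,
                           n_samples=5000, n_replicates=2, seed=6,
                           plant_part_counts={"flower": 5000},
                           plant_type_counts={"herb": 5000})
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.GENUS_CORRECT: p_true, C.UNKNOWN: 1 - p_true})
        records = simulate_records([profile], metadata, taxonomy, config)
        probs, rho_hat = recover_profile(records)
        se = np.sqrt(p_true * (1 - p_true) / 5000)
        assert abs(probs[C.GENUS_CORRECT] - p_true) < 3 * se
        # rho = 0: chance-corrected repeat estimate near zero
        p_same_se = np.sqrt(0.5 * 0.5 / 5000)
        assert rho_hat < 3 * p_same_se / (1 - 0.5)

    def test_rho_recovered(self):
        config = SimConfig(n_families=50, n_genera_per_family=5, n_species_per_genus=4,
                           n_samples=1000, n_replicates=5, seed=7,
                           plant_part_counts={"leaf": 1000},
                           plant_type_counts={"woody": 1000})
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.SPECIES_CORRECT: 0.5, C.UNKNOWN: 0.3, C.MISLEADING: 0.2},
                           rho=0.6)
        records = simulate_records([profile], metadata, taxonomy, config)
        _, rho_hat = recover_profile(records)
        assert rho_hat == pytest.approx(0.6, abs=0.05)

    def test_rho_one_is_recovered_exactly(self):
        config = SimConfig(seed=8)
        taxonomy, metadata = generate_taxonomy(config)
        profile = one_tool({C.SPECIES_CORRECT: 0.6, C.UNKNOWN: 0.4}, rho=1.0)
        records = simulate_records([profile], metadata, taxonomy, config)
        _, rho_hat = recover_profile(records)
        assert rho_hat == 1.0

    def test_recovery_needs_replication(self):
        config = SimConfig(n_replicates=1, seed=9)
        taxonomy, metadata = generate_taxonomy(config)
        records = simulate_records([one_tool({C.UNKNOWN: 1.0})], metadata, taxonomy, config)
        with pytest.raises(Exception):
            recover_profile(records)


class TestDefaultProfiles:
    def test_nine_profiles_spanning_the_spectrum(self):
        profiles = default_profiles()
        assert len(profiles) == 9
        for profile in profiles:
            total = sum(profile.category_probabilities.values())
            assert total == pytest.approx(1.0)

    def test_profile_mass_matches_headline_percentages(self):
        for name, (p100, p80, p50, pmad, _, _) in APP_SUMMARY.items():
            profile = next(p for p in default_profiles() if p.tool_id == name)
            probs = profile.category_probabilities
            assert probs[C.SPECIES_CORRECT] == pytest.approx(p100 / 100, abs=1e-6)
            ge80 = sum(probs[c] for c in (C.SPECIES_CORRECT, C.VERY_CLOSE, C.SMALL_GENUS,
                                          C.GENUS_CORRECT))
            assert ge80 == pytest.approx(p80 / 100, abs=1e-6)
            assert probs[C.MISLEADING] == pytest.approx(pmad / 100, abs=1e-6)

    def test_ranking_recovery_with_ordered_profiles(self):
        """Stochastically ordered tools come out in the right mean order."""
        config = SimConfig(n_families=50, n_genera_per_family=3, n_species_per_genus=2,
                           n_samples=200, n_replicates=5, seed=10,
                           plant_part_counts={"flower": 200},
                           plant_type_counts={"herb": 200})
        taxonomy, metadata = generate_taxonomy(config)
        levels = [0.8, 0.5, 0.2]
        profiles = [
            one_tool({C.SPECIES_CORRECT: lv, C.UNKNOWN: 1 - lv}, tool_id=f"tool{i}")
            for i, lv in enumerate(levels)
        ]
        records = simulate_records(profiles, metadata, taxonomy, config)
        frame = scores_frame(score_records(records))
        means = frame.groupby("tool", sort=False)["first_choice"].mean()
        assert means["tool0"] > means["tool1"] > means["tool2"]
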