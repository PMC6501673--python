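import numpy as np
import pytest

from collide.data_model import validate_dataset
from collide.phylo import Phylogeny
from collide.synthetic import (
    ScenarioConfig,
    generate_scenario,
    simulate_observations,
    simulate_traits,
    simulate_trees,
    write_scenario,
)
from collide.tallies import SeasonWindows


def tip_depths(tree: Phylogeny):
    d = tree.depths()
    return {next(iter(c)): v for c, v in d.items() if len(c) == 1}


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = ScenarioConfig(n_species=10, seed=5, beta_flightcall=2.0)
        p = tmp_path / "scenario.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()), encoding="utf-8")
        cfg2 = ScenarioConfig.from_yaml(p)
        assert cfg2 == cfg
        assert cfg2.config_hash() == cfg.config_hash()

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_species=1)
        with pytest.raises(ValueError):
            ScenarioConfig(tree_model="coalescent")
        with pytest.raises(ValueError):
            ScenarioConfig(light_score_distribution=(1.0,) * 18)


class TestSimulateTrees:
    def test_two_species_cherry(self):
        cfg = ScenarioConfig(n_species=2, n_trees=5, seed=1)
        trees = simulate_trees(cfg)
        for t in trees:
            assert sorted(t.tip_labels) == ["sp001", "sp002"]

    def test_seed_determinism(self):
        cfg = ScenarioConfig(n_species=12, n_trees=4, seed=33)
        a = [t.to_newick() for t in simulate_trees(cfg)]
        b = [t.to_newick() for t in simulate_trees(cfg)]
        assert a == b

    def test_yule_trees_ultrametric(self):
        cfg = ScenarioConfig(n_species=100, n_trees=5, seed=2)
        for tree in simulate_trees(cfg):
            depths = list(tip_depths(tree).values())
            assert max(depths) - min(depths) < 1e-9

    def test_birth_death_trees_ultrametric_with_n_tips(self):
        cfg = ScenarioConfig(n_species=40, tree_model="birth_death", n_trees=3, seed=3)
        for tree in simulate_trees(cfg):
            assert len(tree.tip_labels) == 40
            depths = list(tip_depths(tree).values())
            assert max(depths) - min(depths) < 1e-9

    def test_topology_jitter_produces_variation(self):
        cfg = ScenarioConfig(n_species=20, n_trees=20, tree_nni_moves=5, seed=4)
        trees = simulate_trees(cfg)
        clade_sets = {frozenset(t.clades().keys()) for t in trees}
        assert len(clade_sets) > 1


class TestSimulateTraits:
    def test_zero_rate_keeps_root_state(self):
        cfg = ScenarioConfig(n_species=30, n_trees=1, trait_transition_rate=0.0,
                             root_flight_call="yes", seed=5)
        tree = simulate_trees(cfg)[0]
        traits = simulate_traits(tree, cfg)
        assert all(t.flight_call == "yes" for t in traits)

    def test_high_rate_approaches_stationary_half(self):
        freqs = []
        for seed in range(60):
            cfg = ScenarioConfig(n_species=40, n_trees=1, trait_transition_rate=50.0, seed=seed)
            tree = simulate_trees(cfg)[0]
            traits = simulate_traits(tree, cfg)
            freqs.append(np.mean([t.flight_call == "yes" for t in traits]))
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)

    def test_seed_reproducibility(self):
        cfg = ScenarioConfig(n_species=25, n_trees=1, seed=6)
        tree = simulate_trees(cfg)[0]
        assert simulate_traits(tree, cfg) == simulate_traits(tree, cfg)

    def test_nonfocal_species_appended(self):
        cfg = ScenarioConfig(n_species=10, n_trees=1, n_nonfocal_species=4, seed=7)
        tree = simulate_trees(cfg)[0]
        traits = simulate_traits(tree, cfg)
        assert len(traits) == 14
        classes = {t.migratory_class for t in traits[10:]}
        assert "nocturnal_passerine" not in classes


class TestSimulateObservations:
    def small_cfg(self, **kw):
        base = dict(n_species=20, n_trees=1, n_nights=80, n_days_per_season=40,
                    checklists_per_day=5, seed=8)
        base.update(kw)
        return ScenarioConfig(**base)

    def test_symmetry_without_flightcall_effect(self):
        ratios = []
        for seed in range(10):
            cfg = self.small_cfg(
                beta_flightcall=0.0, seed=seed,
                abundance_lognormal_params=(0.0, 0.0), collision_base_rate=0.5,
                trait_transition_rate=5.0,
            )
            tree = simulate_trees(cfg)[0]
            traits = simulate_traits(tree, cfg)
            _, collisions, _, _ = simulate_observations(traits, cfg)
            yes = {t.species_id for t in traits if t.flight_call == "yes"}
            n_yes = max(len(yes), 1)
            n_no = max(len(traits) - len(yes), 1)
            c_yes = sum(r.species_id in yes for r in collisions) / n_yes
            c_no = sum(r.species_id not in yes for r in collisions) / n_no
            ratios.append(c_yes / max(c_no, 1e-9))
        assert np.median(ratios) == pytest.approx(1.0, rel=0.25)

    def test_flightcall_rate_ratio_e3(self):
        logratios = []
        for seed in range(25):
            cfg = self.small_cfg(
                beta_flightcall=3.0, seed=seed,
                abundance_lognormal_params=(0.0, 0.0), collision_base_rate=0.05,
                trait_transition_rate=5.0,
            )
            tree = simulate_trees(cfg)[0]
            traits = simulate_traits(tree, cfg)
            _, collisions, _, _ = simulate_observations(traits, cfg)
            yes = {t.species_id for t in traits if t.flight_call == "yes"}
            if not yes or len(yes) == len(traits):
                continue
            c_yes = sum(r.species_id in yes for r in collisions) / len(yes)
            c_no = sum(r.species_id not in yes for r in collisions) / (len(traits) - len(yes))
            if c_no > 0 and c_yes > 0:
                logratios.append(np.log(c_yes / c_no))
        se = np.std(logratios, ddof=1) / np.sqrt(len(logratios))
        assert abs(np.mean(logratios) - 3.0) <= 2 * se + 0.1

    def test_light_slopes_close_loop(self):
        from collide.light_models import analyze_light

        cfg = self.small_cfg(
            n_nights=1600, b_light_yes=0.12, b_light_no=0.0,
            collision_base_rate=0.05, seed=11, trait_transition_rate=5.0,
        )
        tree = simulate_trees(cfg)[0]
        traits = simulate_traits(tree, cfg)
        _, _, nights, _ = simulate_observations(traits, cfg)
        result = analyze_light(nights, traits)
        assert result.fits["yes"]["poisson"].slope == pytest.approx(0.12, abs=0.02)
        assert abs(result.fits["no"]["poisson"].slope) < 0.02

    def test_records_validate_cleanly(self):
        cfg = self.small_cfg()
        tree = simulate_trees(cfg)[0]
        traits = simulate_traits(tree, cfg)
        checklists, collisions, nights, _ = simulate_observations(traits, cfg)
        report = validate_dataset(collisions + checklists, traits, SeasonWindows())
        assert report.is_clean

    def test_all_dates_in_windows(self):
        cfg = self.small_cfg()
        tree = simulate_trees(cfg)[0]
        traits = simulate_traits(tree, cfg)
        _, collisions, nights, _ = simulate_observations(traits, cfg)
        w = SeasonWindows()
        assert all(w.assign(n.date) != "outside" for n in nights)
        assert len(nights) == cfg.n_nights


class TestScenarioIO:
    def test_write_scenario_outputs_parse_back(self, tmp_path):
        from collide.data_model import read_records
        from collide.phylo import parse_newick_list

        cfg = ScenarioConfig(n_species=10, n_trees=5, n_nights=40,
                             n_days_per_season=20, seed=13)
        study = generate_scenario(cfg)
        write_scenario(study, tmp_path)
        for name, schema in [("collisions.csv", "collision"), ("checklists.csv", "checklist"),
                             ("traits.csv", "traits"), ("nights.csv", "nights")]:
            result = read_records(tmp_path / name, schema)
            assert not result.errors
        trees = parse_newick_list((tmp_path / "trees.nwk").read_text())
        assert len(trees) == 5
        assert (tmp_path / "provenance.yaml").exists()

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = ScenarioConfig(n_species=8, n_trees=3, n_nights=30,
                             n_days_per_season=15, seed=21)
        a, b = tmp_path / "a", tmp_path / "b"
        write_scenario(generate_scenario(cfg), a)
        write_scenario(generate_scenario(cfg), b)
        for f in sorted(a.iterdir()):
            assert f.read_bytes() == (b / f.name).read_bytes()
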