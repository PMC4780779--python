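import math

import numpy as np
import pytest

from oracles import sankoff_parsimony_score
from nichelimits.backbone_tree import (
    is_ultrametric,
    leaf_labels,
    parse_backbone_spec,
    parse_newick,
    read_assignments,
)
from nichelimits.niche_extremes import trim_extremes
from nichelimits.occurrence_climate import (
    attach_climate,
    read_ascii_grid,
    read_occurrence_table,
    sample_grid,
)
from nichelimits.pgls_core import Family, TreeData, build_design, fit_pgls
from nichelimits.synthetic_data import (
    ScenarioConfig,
    ScenarioTruth,
    assign_states_by_clades,
    make_scenario,
    sigma_for_power,
    simulate_climate_grid,
    simulate_occurrences,
    simulate_tip_values,
    simulate_yule_tree,
)


class TestYuleTree:
    def test_basic_shape(self, rng):
        tree = simulate_yule_tree(3, 1.0, rng)
        assert len(leaf_labels(tree)) == 3
        assert sorted(leaf_labels(tree)) == ["sp0001", "sp0002", "sp0003"]
        assert is_ultrametric(tree)

    def test_same_seed_same_tree(self):
        a = simulate_yule_tree(20, 1.0, 5)
        b = simulate_yule_tree(20, 1.0, 5)
        from nichelimits.backbone_tree import write_newick

        assert write_newick(a) == write_newick(b)
        assert write_newick(a) != write_newick(simulate_yule_tree(20, 1.0, 6))

    def test_mean_height_matches_theory(self):
        # E[height] of a Yule tree grown to n tips (with the final stretch
        # drawn from Exp(n*rate)) is (1/rate) * sum_{k=2}^{n} 1/k ... plus the
        # final Exp(n*rate) extension: total sum_{k=2}^{n} 1/k + 1/n applies
        # when the last wait is included; here the construction includes a
        # final Exp(n*rate) wait, giving (1/rate)(sum_{k=2}^{n} 1/k + 1/n).
        n, rate, reps = 12, 1.3, 500
        rng = np.random.default_rng(202)
        heights = []
        for _ in range(reps):
            tree = simulate_yule_tree(n, rate, rng)
            leaf = next(tree.leaf_node_iter())
            h = 0.0
            node = leaf
            while node.parent_node is not None:
                h += node.edge.length
                node = node.parent_node
            heights.append(h)
        expected = (sum(1.0 / k for k in range(2, n + 1)) + 1.0 / n) / rate
        assert np.mean(heights) == pytest.approx(expected, rel=0.10)

    @pytest.mark.parametrize("n", [0, 1])
    def test_too_few_tips_rejected(self, n):
        with pytest.raises(ValueError):
            simulate_yule_tree(n, 1.0, 1)


class TestStateAssignment:
    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_parsimony_score_equals_transition_count(self, random_trees, k):
        for tree in random_trees(3, 40, seed=107):
            states, sets = assign_states_by_clades(tree, k, seed=k)
            assert len(sets) == k
            assert set(states.values()) == {"C3", "C4"}
            assert sankoff_parsimony_score(tree, states) == k

    def test_flipped_sets_are_disjoint_clades(self, random_trees):
        tree = random_trees(1, 40, seed=109)[0]
        states, sets = assign_states_by_clades(tree, 4, seed=2)
        c4 = {l for l, s in states.items() if s == "C4"}
        assert c4 == set().union(*sets)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_impossible_request_rejected(self, random_trees):
        tree = random_trees(1, 10, seed=111)[0]
        with pytest.raises(ValueError):
            assign_states_by_clades(tree, 5, seed=1)  # needs < n/2


class TestTipValues:
    def test_zero_variance_returns_exact_means(self, random_trees):
        tree = random_trees(1, 15, seed=113)[0]
        states, _ = assign_states_by_clades(tree, 2, seed=3)
        labels, y = simulate_tip_values(
            tree, states, Family.BROWNIAN, None, 5.0, 2.0, 0.0, seed=1
        )
        for l, v in zip(labels, y):
            assert v == (7.0 if states[l] == "C4" else 5.0)

    def test_empirical_covariance_matches_sigma2_v(self):
        tree = parse_newick(
            "((sp1:1,sp2:1):1,((sp3:0.5,sp4:0.5):1,sp5:1.5):0.5);"
        )
        td = TreeData(tree)
        states = {l: ("C4" if l in ("sp1", "sp2") else "C3") for l in td.labels}
        sigma2 = 1.7
        rng = np.random.default_rng(777)
        draws = np.array([
            simulate_tip_values(td, states, Family.BROWNIAN, None, 0.0, 0.0, sigma2, rng)[1]
            for _ in range(4000)
        ])
        emp = np.cov(draws.T)
        # per-entry SE of a sample covariance at 4000 draws is about
        # sqrt(v_ii*v_jj + v_ij^2)/63 ~= 0.05-0.08 here; allow ~4 SE
        np.testing.assert_allclose(emp, sigma2 * td.V, rtol=0.1, atol=0.25)

    def test_power_rule_delivers_target_power(self, random_trees):
        tree = random_trees(1, 120, seed=127)[0]
        td = TreeData(tree)
        states, _ = assign_states_by_clades(tree, 4, seed=5)
        beta1 = 1.61
        sigma = sigma_for_power(td, states, beta1, power=0.9, alpha=0.05)
        rng = np.random.default_rng(901)
        X = build_design([states[l] for l in td.labels])
        hits = 0
        reps = 200
        for _ in range(reps):
            _, y = simulate_tip_values(
                td, states, Family.BROWNIAN, None, 0.0, beta1, sigma**2, rng
            )
            hits += fit_pgls(y, X, td, Family.BROWNIAN).p_value <= 0.05
        # binomial sd at p=0.9, n=200 is ~0.021; allow 3 sd
        assert hits / reps == pytest.approx(0.9, abs=0.065)

    def test_power_rule_rejects_degenerate_inputs(self, random_trees):
        tree = random_trees(1, 10, seed=131)[0]
        labels = leaf_labels(tree)
        with pytest.raises(ValueError):
            sigma_for_power(tree, {l: "C3" for l in labels}, 1.0)
        with pytest.raises(ValueError):
            sigma_for_power(tree, {l: "C3" for l in labels}, 0.0)


class TestGrids:
    def test_noiseless_latitude_gradient(self):
        grid = simulate_climate_grid("MTWQ", (0, 0, 1.0, 4, 5), 10.0, 30.0, 0.0, 1)
        np.testing.assert_allclose(grid.values[0], 30.0)   # north
        np.testing.assert_allclose(grid.values[-1], 10.0)  # south
        np.testing.assert_allclose(grid.values[:, 0], np.linspace(30, 10, 5))

    def test_longitude_axis(self):
        grid = simulate_climate_grid("AI", (0, 0, 1.0, 5, 3), 0.2, 1.0, 0.0, 1, axis="lon")
        np.testing.assert_allclose(grid.values[0], np.linspace(0.2, 1.0, 5))
        np.testing.assert_allclose(grid.values[0], grid.values[-1])

    def test_ai_noise_clipped_at_zero(self):
        grid = simulate_climate_grid("AI", (0, 0, 1.0, 30, 30), 0.0, 0.1, 1.0, 11, axis="lon")
        assert grid.values.min() >= 0.0

    def test_slope_recovery_under_noise(self):
        grid = simulate_climate_grid("MTWQ", (0, 0, 1.0, 50, 200), 0.0, 100.0, 1.0, 13)
        row_means = grid.values.mean(axis=1)
        slope = np.polyfit(np.arange(200), row_means, 1)[0]
        assert slope == pytest.approx(-100.0 / 199, rel=0.02)

    def test_inverted_gradient_rejected(self):
        with pytest.raises(ValueError):
            simulate_climate_grid("MTWQ", (0, 0, 1, 4, 4), 30.0, 10.0)


class TestOccurrences:
    def test_sampled_values_stay_inside_interval(self):
        grid = simulate_climate_grid("MTWQ", (0, 0, 0.5, 40, 40), 0.0, 40.0, 0.0, 3)
        pts = simulate_occurrences("sp", (12.0, 20.0), grid, 300, seed=4)
        vals = [sample_grid(grid, x, y) for x, y in pts]
        assert all(v is not None and 12.0 <= v <= 20.0 for v in vals)

    def test_trimmed_extremes_converge_into_interval(self):
        grid = simulate_climate_grid("MTWQ", (0, 0, 0.5, 40, 40), 0.0, 40.0, 0.0, 3)
        pts = simulate_occurrences("sp", (12.0, 20.0), grid, 500, seed=9)
        vals = [sample_grid(grid, x, y) for x, y in pts]
        lo, hi = trim_extremes(vals, 0.05)
        assert 12.0 <= lo <= hi <= 20.0
        assert lo - 12.0 < 2.0 and 20.0 - hi < 2.0

    def test_empty_interval_rejected(self):
        grid = simulate_climate_grid("MTWQ", (0, 0, 0.5, 10, 10), 0.0, 40.0, 0.0, 3)
        with pytest.raises(ValueError, match="no grid cells"):
            simulate_occurrences("sp", (100.0, 110.0), grid, 10, seed=1)


class TestMakeScenario:
    def test_bundle_files_parse_and_agree(self, small_scenario):
        out = small_scenario["dir"]
        truth = small_scenario["truth"]
        cfg = small_scenario["scenario_config"]

        records, dropped = read_occurrence_table(str(out / "occurrences.csv"))
        assert dropped == 0
        species = {r.species_id for r in records}
        assert species == set(truth.states)
        assert len(records) == len(species) * cfg.n_records
        # states in the table match the truth record
        for r in records:
            assert r.state == truth.states[r.species_id]

        tree = parse_newick((out / "tree.nwk").read_text())
        assert len(leaf_labels(tree)) == cfg.n_sampled
        spec = parse_backbone_spec((out / "backbone.txt").read_text())
        assert spec.roots and set().union(
            *(c.full_species_set() for c in spec.roots)
        ) == set(leaf_labels(tree))
        assignments = read_assignments(str(out / "assignments.csv"))
        assert len(assignments) == cfg.n_grafted
        clade_names = {c.name for c in spec.roots}
        assert set(assignments.values()) <= clade_names

        again = ScenarioTruth.from_json(out / "truth.json")
        assert again.states == truth.states
        assert again.effects == truth.effects

    def test_grids_cover_sampled_occurrences(self, small_scenario):
        out = small_scenario["dir"]
        truth = small_scenario["truth"]
        grids = {
            v: read_ascii_grid((out / f"grid_{v}.asc").read_text(), v)
            for v in ("AI", "MTWQ", "MTCQ")
        }
        records, _ = read_occurrence_table(str(out / "occurrences.csv"))
        samples = attach_climate(records, grids)
        for s in samples:
            for var in ("AI", "MTWQ", "MTCQ"):
                assert s.values[var] is not None
                lo, hi = truth.intervals[s.record.species_id][var]
                assert lo - 1e-9 <= s.values[var] <= hi + 1e-9

    def test_zero_effect_rows_have_zero_beta1(self, small_scenario):
        eff = small_scenario["truth"].effects
        for key in ("MTWQ_min", "MTCQ_max", "AI_min", "AI_max"):
            assert eff[key]["beta1"] == 0.0
        assert eff["MTWQ_max"]["beta1"] == pytest.approx(1.61)
        assert eff["MTCQ_min"]["beta1"] < 0  # inherited, opposite sign

    def test_same_seed_reproduces_bundle_bytes(self, tmp_path):
        cfg = ScenarioConfig(n_sampled=16, n_grafted=8, n_transitions=2, n_records=20)
        t1 = make_scenario(cfg, seed=7, out_dir=tmp_path / "a")
        t2 = make_scenario(cfg, seed=7, out_dir=tmp_path / "b")
        t3 = make_scenario(cfg, seed=8, out_dir=tmp_path / "c")
        for name in ("occurrences.csv", "tree.nwk", "backbone.txt",
                     "assignments.csv", "grid_MTWQ.asc"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert t1.states == t2.states
        assert (
            (tmp_path / "a" / "occurrences.csv").read_bytes()
            != (tmp_path / "c" / "occurrences.csv").read_bytes()
        )
        assert t1.states != t3.states or t1.intervals != t3.intervals
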