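"""Stable-state solver: equations, blocks, cubes, sampling, oracle equality."""

import random
from itertools import product

import pytest

from logicnet import (BooleanModel, brute_force_fixed_points,
                      consistency_equations, decompose, solve)
from logicnet.expr import And, Not, Or, Var, parse_expression
from logicnet.fixedpoints import Cube, CubeSet

from conftest import canon_states, random_network, random_rule_model
from logicnet import build_model


class TestBruteForce:
    def test_mutual_activation(self, mutual_activation):
        fps = brute_force_fixed_points(mutual_activation)
        assert canon_states(fps) == [(0, 0), (1, 1)]

    def test_negative_loop_has_none(self, toy_negative_loop):
        assert brute_force_fixed_points(toy_negative_loop).cardinality == 0

    def test_all_free_inputs(self):
        m = BooleanModel(["a", "b", "c"], {n: Var(n) for n in "abc"})
        assert brute_force_fixed_points(m).cardinality == 8

    def test_guard_refuses_large_models(self):
        n = 23
        m = BooleanModel([f"x{i}" for i in range(n)],
                         {f"x{i}": Var(f"x{i}") for i in range(n)})
        with pytest.raises(ValueError, match="refused"):
            brute_force_fixed_points(m)


class TestEquationsAndBlocks:
    def test_tautology_for_free_input(self):
        m = BooleanModel(["a", "b"], {"a": Var("a"), "b": Var("a")})
        eqs = {e.node: e for e in consistency_equations(m)}
        assert eqs["a"].is_tautology
        assert not eqs["b"].is_tautology

    def test_contradiction_detected(self):
        m = BooleanModel(["a"], {"a": Not.of(Var("a"))})
        assert consistency_equations(m)[0].is_contradiction

    def test_disjoint_systems_stay_separate_blocks(self):
        funcs = {}
        nodes = []
        for i in range(3):
            x, y = f"x{i}", f"y{i}"
            nodes += [x, y]
            funcs[x] = Var(y)
            funcs[y] = Var(x)
        m = BooleanModel(nodes, funcs)
        blocks = decompose(m, budget=2)
        assert len(blocks) == 3
        assert all(len(b.support) == 2 for b in blocks)

    def test_fully_coupled_system_is_one_block(self):
        nodes = [f"x{i}" for i in range(5)]
        funcs = {n: And.of(*(Var(o) for o in nodes if o != n)) for n in nodes}
        m = BooleanModel(nodes, funcs)
        assert len(decompose(m, budget=5)) == 1

    def test_budget_smaller_than_one_equation_errors(self):
        nodes = [f"x{i}" for i in range(5)]
        funcs = {n: Var(nodes[0]) for n in nodes}
        funcs[nodes[0]] = And.of(*(Var(o) for o in nodes[1:]))
        m = BooleanModel(nodes, funcs)
        with pytest.raises(ValueError, match="budget"):
            decompose(m, budget=3)

    def test_blocks_cover_all_nontrivial_equations(self):
        for seed in range(10):
            m = build_model(random_network(seed))
            eqs = [e for e in consistency_equations(m) if not e.is_tautology]
            blocks = decompose(m, budget=25)
            covered = [e.node for b in blocks for e in b.equations]
            assert sorted(covered) == sorted(e.node for e in eqs)


class TestSolve:
    def test_matches_oracle_convention_models(self):
        for seed in range(50):
            m = build_model(random_network(seed, n_max=12))
            assert canon_states(solve(m)) == canon_states(
                brute_force_fixed_points(m))

    def test_matches_oracle_explicit_rule_models(self):
        for seed in range(50):
            m = random_rule_model(seed, n_max=10)
            assert canon_states(solve(m)) == canon_states(
                brute_force_fixed_points(m))

    def test_contradictory_model_empty(self, toy_negative_loop):
        fps = solve(toy_negative_loop)
        assert fps.cardinality == 0 and not fps

    def test_free_inputs_with_constant_cascade_compact_to_one_cube(self):
        """Inputs that leave downstream rules constant stay free and the
        solution compacts to a single cube of cardinality 2^3."""
        m = BooleanModel(
            ["i1", "i2", "i3", "a", "b"],
            {"i1": Var("i1"), "i2": Var("i2"), "i3": Var("i3"),
             "a": parse_expression("i1 & !i1 | 0"),
             "b": parse_expression("a")})
        fps = solve(m)
        assert fps.cardinality == 8
        assert fps.n_cubes == 1
        assert fps.cubes[0].free == {"i1", "i2", "i3"}
        assert canon_states(fps) == canon_states(brute_force_fixed_points(m))

    def test_every_solution_is_a_fixed_point(self):
        for seed in (2, 5, 11):
            m = build_model(random_network(seed, n_max=14))
            for s in solve(m).expand(limit=1 << 14):
                assert m.is_fixed_point(s)

    def test_fixed_under_asynchronous_updates_too(self):
        """Stable states are scheme-independent: each solution is fixed
        under every single-node update as well."""
        for seed in (1, 7):
            m = build_model(random_network(seed, n_max=10))
            for s in solve(m).expand(limit=1 << 12):
                for n in m.nodes:
                    assert m.functions[n].evaluate(s) == s[n]

    def test_cardinality_invariant_to_node_order_and_budget(self):
        for seed in (0, 3, 6, 9):
            m = random_rule_model(seed, n_max=9)
            card = solve(m).cardinality
            rng = random.Random(seed)
            nodes = list(m.nodes)
            rng.shuffle(nodes)
            reordered = BooleanModel(nodes, dict(m.functions))
            assert solve(reordered).cardinality == card
            for budget in (6, 10, 20):
                assert solve(m, budget=budget).cardinality == card


class TestCubeSet:
    def test_expand_single_cube(self):
        cs = CubeSet(["A", "B"], [Cube.make({"A": 1}, {"B"})])
        states = sorted(tuple(sorted(s.items())) for s in cs.expand())
        assert states == [(("A", 1), ("B", 0)), (("A", 1), ("B", 1))]

    def test_expand_respects_limit(self):
        cs = CubeSet(["A", "B"], [Cube.make({}, {"A", "B"})])
        with pytest.raises(ValueError, match="limit"):
            list(cs.expand(limit=3))

    def test_empty_expansion(self):
        assert list(CubeSet(["A"], []).expand()) == []

    def test_gray_order_is_deterministic(self):
        cs = CubeSet(["a", "b", "c"], [Cube.make({}, {"a", "b", "c"})])
        assert list(cs.expand()) == list(cs.expand())

    def test_csv_roundtrip(self, tmp_path):
        cs = CubeSet(["A", "B", "C"],
                     [Cube.make({"A": 1, "B": 0}, {"C"}),
                      Cube.make({"A": 0}, {"B", "C"})])
        p = tmp_path / "cubes.csv"
        cs.to_csv(p)
        again = CubeSet.from_csv(p, ["A", "B", "C"])
        assert canon_states(again) == canon_states(cs)


class TestSampling:
    def test_full_sample_is_exact_set(self):
        m = BooleanModel(["a", "b", "c"], {n: Var(n) for n in "abc"})
        fps = solve(m)
        sample = fps.sample_states(8, seed=0)
        assert sorted(tuple(s[n] for n in fps.nodes) for s in sample) == \
            canon_states(fps)

    def test_seed_reproducibility(self):
        m = random_rule_model(4)
        fps = solve(m)
        n = min(fps.cardinality, 5)
        if n == 0:
            pytest.skip("seed produced an empty model (not the point here)")
        assert fps.sample_states(n, seed=9) == fps.sample_states(n, seed=9)

    def test_oversampling_rejected(self, mutual_activation):
        fps = solve(mutual_activation)
        with pytest.raises(ValueError, match="sample"):
            fps.sample_states(3, seed=0)

    def test_sampled_frequencies_match_exact_rates(self):
        """Per-node ON frequencies in a 10k sample lie within 3 sigma of
        the exact cube-analytic rates."""
        m = BooleanModel(
            [f"i{j}" for j in range(6)] + ["z"],
            {**{f"i{j}": Var(f"i{j}") for j in range(6)},
             "z": And.of(Var("i0"), Var("i1"))})
        fps = solve(m)
        assert fps.cardinality == 64
        n = 10_000
        # with replacement across repeats is not available: sample many
        # small without-replacement draws instead
        counts = {node: 0 for node in fps.nodes}
        draws = 0
        for rep in range(200):
            for s in fps.sample_states(50, seed=rep):
                draws += 1
                for node, v in s.items():
                    counts[node] += v
        from logicnet import rate_of_one
        rates = rate_of_one(fps)
        for node in fps.nodes:
            p = rates[node]
            sigma = (p * (1 - p) / draws) ** 0.5
            assert abs(counts[node] / draws - p) <= max(3 * sigma, 0.02)
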