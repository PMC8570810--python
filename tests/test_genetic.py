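"""Genetic search: ancestry layers, decoding, fitness ordering, evolution."""

import pytest

from targetctl.genetic import (
    GAParams,
    ancestors_within,
    build_walk,
    decode,
    fitness,
    ga_control,
)
from targetctl.model import (
    ControlProblem,
    ControlSolution,
    DirectedNetwork,
    check_path_compatibility,
)
from targetctl.oracle import RankTestParams, brute_force_minimum_inputs, target_generic_rank
from targetctl.synthetic import random_digraph, sample_problem, toy_fixture

GA_FAST = dict(population_size=24, max_generations=60, stagnation_limit=15)


class TestAncestorsWithin:
    def test_chain_layers(self):
        net, _ = toy_fixture("chain")
        assert ancestors_within(net, "c", 2) == {
            "c": frozenset({0}), "b": frozenset({1}), "a": frozenset({2})}

    def test_in_degree_zero_target_sees_only_itself(self):
        net, _ = toy_fixture("chain")
        assert ancestors_within(net, "a", 5) == {"a": frozenset({0})}

    def test_cycle_layers_follow_parity(self):
        net, _ = toy_fixture("cycle")
        anc = ancestors_within(net, "a", 3)
        assert anc["a"] == frozenset({0, 2}) and anc["b"] == frozenset({1, 3})


class TestBuildWalkAndDecode:
    def test_walk_is_shortest_and_lexicographic(self):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("a", "c"), ("b", "t"), ("c", "t")])
        walk = build_walk(net, "a", "t", 2)
        assert walk.nodes == ("a", "b", "t")  # 'b' < 'c'

    def test_infeasible_length_rejected(self):
        net, _ = toy_fixture("chain")
        with pytest.raises(ValueError):
            build_walk(net, "a", "c", 1)

    def test_chain_shared_input_decodes_conflict_free(self):
        net, prob = toy_fixture("chain")
        sol = decode((("b", "a"), ("c", "a")), prob)
        assert isinstance(sol, ControlSolution) and sol.inputs == {"a"}

    def test_star_shared_input_is_irreparable(self):
        net, prob = toy_fixture("star")
        result = decode((("b", "a"), ("c", "a")), prob)
        assert result == 1  # both walks pin 'a' at layer 1, no alternative layer

    def test_self_assignment_always_feasible(self, toy):
        _, _, prob = toy
        genes = tuple((t, t) for t in sorted(prob.targets))
        sol = decode(genes, prob)
        assert isinstance(sol, ControlSolution) and sol.inputs == prob.targets

    def test_repair_reroutes_through_longer_walk(self):
        # both targets driven from u; t2's walk can stretch via the x-detour
        net = DirectedNetwork.from_edges(
            [("u", "t1"), ("u", "t2"), ("u", "x"), ("x", "t2")])
        prob = ControlProblem(network=net, targets=frozenset({"t1", "t2"}))
        sol = decode((("t1", "u"), ("t2", "u")), prob)
        assert isinstance(sol, ControlSolution) and sol.inputs == {"u"}

    def test_non_ancestor_gene_is_hard_error(self):
        net, prob = toy_fixture("chain")
        with pytest.raises(ValueError):
            decode((("b", "c"), ("c", "a")), prob)


class TestFitness:
    def test_ordering(self):
        net, prob = toy_fixture("chain")
        feasible = decode((("b", "a"), ("c", "a")), prob)
        assert isinstance(feasible, ControlSolution)
        assert fitness(feasible, prob) < fitness(1, prob)  # any feasible beats infeasible
        selfy = decode((("b", "b"), ("c", "c")), prob)
        assert fitness(feasible, prob) < fitness(selfy, prob)  # |I|=1 beats |I|=2

    def test_preferred_sources_break_ties(self):
        net = toy_fixture("chain")[0]
        prob = ControlProblem(network=net, targets=frozenset({"c"}),
                              preferred_sources=frozenset({"a"}))
        via_pref = decode((("c", "a"),), prob)
        via_plain = decode((("c", "b"),), prob)
        assert fitness(via_pref, prob) < fitness(via_plain, prob)


class TestGAControl:
    def test_chain_finds_the_optimum(self):
        _, prob = toy_fixture("chain")
        result = ga_control(prob, GAParams(rng_seed=1, **GA_FAST))
        assert result.solutions[0].inputs == {"a"}

    def test_star_optimum_is_two(self):
        _, prob = toy_fixture("star")
        result = ga_control(prob, GAParams(rng_seed=1, **GA_FAST))
        assert len(result.solutions[0].inputs) == 2

    def test_best_fitness_never_worsens(self):
        net = random_digraph(12, "er", 0.15, rng_seed=9)
        prob = sample_problem(net, n_targets=4, n_preferred=2, rng_seed=9)
        result = ga_control(prob, GAParams(rng_seed=9, **GA_FAST))
        hist = result.best_history
        assert all(b <= a for a, b in zip(hist, hist[1:]))

    def test_reproducible_for_fixed_seed(self):
        net = random_digraph(12, "er", 0.15, rng_seed=3)
        prob = sample_problem(net, n_targets=3, n_preferred=2, rng_seed=3)
        r1 = ga_control(prob, GAParams(rng_seed=5, **GA_FAST))
        r2 = ga_control(prob, GAParams(rng_seed=5, **GA_FAST))
        assert [s.paths for s in r1.solutions] == [s.paths for s in r2.solutions]
        assert r1.best_history == r2.best_history

    @pytest.mark.parametrize("seed", range(10))
    def test_solutions_compatible_and_rank_certified(self, seed):
        net = random_digraph(10, "er", 0.18, rng_seed=50 + seed)
        prob = sample_problem(net, n_targets=3, n_preferred=2, rng_seed=seed)
        result = ga_control(prob, GAParams(rng_seed=seed, **GA_FAST))
        assert result.controllable
        for sol in result.solutions:
            assert check_path_compatibility(sol) == []
            assert target_generic_rank(net, sol.inputs, prob.targets,
                                       RankTestParams(rng_seed=seed)) == len(prob.targets)

    def test_uncontrollable_when_self_inputs_forbidden_and_no_ancestors(self):
        net = DirectedNetwork.from_edges([("a", "b")], extra_nodes=["c"])
        prob = ControlProblem(network=net, targets=frozenset({"c"}),
                              allow_self_inputs=False)
        result = ga_control(prob, GAParams(rng_seed=0, **GA_FAST))
        assert not result.controllable and result.solutions == []

    def test_matches_brute_force_on_small_instances(self):
        hits = 0
        total = 12
        for seed in range(total):
            net = random_digraph(6, "er", 0.25, rng_seed=200 + seed)
            prob = sample_problem(net, n_targets=2, n_preferred=1, rng_seed=seed)
            best, _ = brute_force_minimum_inputs(
                net, prob.targets, params=RankTestParams(rng_seed=seed))
            result = ga_control(prob, GAParams(rng_seed=seed, **GA_FAST))
            assert result.controllable
            if len(result.solutions[0].inputs) == best:
                hits += 1
        assert hits >= int(0.8 * total)
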