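"""Objective evaluation, greedy hill climbing and the cost sweep."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from subnetx.optimizer import (
    cost_sweep,
    exhaustive_optimize,
    greedy_optimize,
    is_local_optimum,
    objective,
)
from subnetx.pathfinder import RunConfig, k_best_paths
from subnetx.pathprob import SubNetwork, union_probability
from subnetx.synthdata import ScenarioSpec, generate_scenario
from subnetx import (
    build_probabilistic_network,
    read_expression,
    read_gene_list,
    read_network,
)

from conftest import make_pnet, random_pnet

CFG = RunConfig(mode="downstream", cost=0.1, k=5)


@pytest.fixture
def toy_pathsets():
    """Three list genes joined through a hub; hand-set probabilities.

    a -> h (0.9), h -> b (0.8), h -> c (0.5), a -> x -> b detour (0.6*0.7).
    """
    pnet = make_pnet(
        [
            ("a", "h", "pd", True),
            ("h", "b", "pd", True),
            ("h", "c", "pd", True),
            ("a", "x", "pd", True),
            ("x", "b", "pd", True),
            ("c", "z", "pd", True),  # dead end: on no list-to-list path
        ],
        probs={0: 0.9, 1: 0.8, 2: 0.5, 3: 0.6, 4: 0.7, 5: 0.3},
    )
    return k_best_paths(pnet, ["a", "b", "c"], CFG)


def _small_scenario_pathsets(seed, mode="upstream", cost=0.01, tmp_dir=None):
    spec = ScenarioSpec(
        n_genes=60,
        n_pd=40,
        n_pp=50,
        n_met=25,
        n_regulators=2,
        targets_per_regulator=8,
        seed=seed,
    )
    bundle = generate_scenario(spec, tmp_dir)
    net = read_network(bundle.network_path)
    expr = read_expression(bundle.expression_path)
    genes = read_gene_list(bundle.gene_list_path)
    pnet = build_probabilistic_network(net, expr)
    cfg = RunConfig(mode=mode, cost=cost)
    return k_best_paths(pnet, genes, cfg), cfg, bundle


class TestObjective:
    def test_empty_subnetwork_is_zero(self, toy_pathsets):
        obj = objective(SubNetwork(edges=frozenset()), toy_pathsets, CFG)
        assert obj.total == 0.0
        assert obj.connectivity_term == 0.0

    def test_hand_computed_value(self, toy_pathsets):
        """Full universe at cost 0.1: check against hand arithmetic."""
        edges = sorted(toy_pathsets.all_edges())
        sub = SubNetwork(edges=frozenset(edges))
        obj = objective(sub, toy_pathsets, CFG)
        # From a: paths a->h->b (.72), a->x->b (.42), a->h->c (.45);
        # union for shared-edge family computed independently below.
        conn_a = union_probability(toy_pathsets.by_start["a"], toy_pathsets.network)
        # b and c have no downstream paths to other list genes.
        assert obj.connectivity_term == pytest.approx(conn_a)
        assert obj.penalty_term == pytest.approx(0.1 * len(edges))
        assert obj.total == pytest.approx(conn_a - 0.1 * len(edges))

    def test_zero_cost_connectivity_only(self, toy_pathsets):
        cfg = dataclasses.replace(CFG, cost=0.0)
        sub = SubNetwork(edges=frozenset(toy_pathsets.all_edges()))
        obj = objective(sub, toy_pathsets, cfg)
        assert obj.penalty_term == 0.0
        assert obj.total == obj.connectivity_term


class TestGreedy:
    def test_prohibitive_cost_returns_empty(self, toy_pathsets):
        # Cost above |L| makes every addition losing.
        cfg = dataclasses.replace(CFG, cost=4.0)
        res = greedy_optimize(toy_pathsets, cfg)
        assert res.subnetwork.n_edges == 0
        assert res.objective.total == 0.0

    def test_zero_cost_reaches_full_universe_objective(self, toy_pathsets):
        cfg = dataclasses.replace(CFG, cost=0.0)
        res = greedy_optimize(toy_pathsets, cfg)
        full = objective(
            SubNetwork(edges=frozenset(toy_pathsets.all_edges())), toy_pathsets, cfg
        )
        assert res.objective.total == pytest.approx(full.total)

    def test_objective_never_negative(self, toy_pathsets):
        for cost in (0.0, 0.05, 0.2, 1.0, 5.0):
            cfg = dataclasses.replace(CFG, cost=cost)
            res = greedy_optimize(toy_pathsets, cfg)
            assert res.objective.total >= -1e-12

    def test_result_is_local_optimum(self, toy_pathsets):
        res = greedy_optimize(toy_pathsets, CFG)
        assert is_local_optimum(res, toy_pathsets, CFG)

    def test_deterministic_trace(self, toy_pathsets):
        r1 = greedy_optimize(toy_pathsets, CFG)
        r2 = greedy_optimize(toy_pathsets, CFG)
        assert r1.moves == r2.moves
        assert r1.subnetwork == r2.subnetwork

    def test_connectivity_monotone_along_addition_prefix(self, toy_pathsets):
        res = greedy_optimize(toy_pathsets, CFG)
        conn_values = []
        edges = set()
        for mv in res.moves:
            if mv.op != "add":
                break
            edges |= set(mv.edges)
            obj = objective(SubNetwork(edges=frozenset(edges)), toy_pathsets, CFG)
            conn_values.append(obj.connectivity_term)
        assert conn_values == sorted(conn_values)

    def test_gain_trace_matches_objective_steps(self, toy_pathsets):
        res = greedy_optimize(toy_pathsets, CFG)
        prev = 0.0
        for mv in res.moves:
            assert mv.gain > 0
            assert mv.objective_after == pytest.approx(prev + mv.gain)
            prev = mv.objective_after

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_on_small_instances(self, seed):
        """Greedy is locally optimal; report its gap to the global optimum."""
        rng = np.random.default_rng(300 + seed)
        pnet = random_pnet(rng, 7, 12)
        genes = sorted(pnet.network.nodes)[:4]
        cfg = RunConfig(mode="downstream", cost=0.05, k=5, max_path_length=3)
        try:
            ps = k_best_paths(pnet, genes, cfg)
        except ValueError:
            pytest.skip("no list genes connected in this draw")
        if len(ps.all_edges()) > 12:
            cfg = dataclasses.replace(cfg, max_path_length=2)
            ps = k_best_paths(pnet, genes, cfg)
        if not ps.by_pair or len(ps.all_edges()) > 12:
            pytest.skip("instance too large or empty")
        greedy = greedy_optimize(ps, cfg)
        best = exhaustive_optimize(ps, cfg)
        gap = best.objective.total - greedy.objective.total
        assert gap >= -1e-9  # exhaustive is an upper bound
        assert is_local_optimum(greedy, ps, cfg)
        print(f"seed {seed}: greedy gap to global optimum = {gap:.3e}")

    def test_empty_universe_warns_and_returns_empty(self, caplog):
        import logging

        pnet = make_pnet([("a", "b", "pd", True), ("c", "d", "pd", True)])
        ps = k_best_paths(pnet, ["a", "c"], CFG)
        assert not ps.by_pair
        with caplog.at_level(logging.WARNING):
            res = greedy_optimize(ps, CFG)
        assert res.subnetwork.n_edges == 0


class TestCostSweep:
    def test_extreme_costs(self, toy_pathsets):
        results = cost_sweep(toy_pathsets, CFG, [10.0, 0.0])
        assert results[0].subnetwork.n_edges == 0
        full = objective(
            SubNetwork(edges=frozenset(toy_pathsets.all_edges())),
            toy_pathsets,
            dataclasses.replace(CFG, cost=0.0),
        )
        assert results[1].objective.total == pytest.approx(full.total)

    def test_single_cost_equals_greedy(self, toy_pathsets):
        (res,) = cost_sweep(toy_pathsets, CFG, [0.1])
        assert res.subnetwork == greedy_optimize(toy_pathsets, CFG).subnetwork

    def test_three_costs_report_sizes(self, toy_pathsets):
        results = cost_sweep(toy_pathsets, CFG, [1.0, 0.1, 0.0])
        assert len(results) == 3
        assert all(r.subnetwork.n_edges >= 0 for r in results)

    def test_validation_errors(self, toy_pathsets):
        with pytest.raises(ValueError, match="empty"):
            cost_sweep(toy_pathsets, CFG, [])
        with pytest.raises(ValueError, match="decreasing"):
            cost_sweep(toy_pathsets, CFG, [0.1, 0.1])
        with pytest.raises(ValueError, match="nonnegative"):
            cost_sweep(toy_pathsets, CFG, [0.1, -0.2])

    def test_mean_size_nonincreasing_in_cost(self, tmp_path):
        """Across the scenario suite, mean edge count shrinks as cost grows."""
        costs = [0.2, 0.05, 0.005]
        sizes = {c: [] for c in costs}
        for seed in range(3):
            ps, cfg, _ = _small_scenario_pathsets(seed, tmp_dir=tmp_path / str(seed))
            for res in cost_sweep(ps, cfg, costs):
                sizes[res.cost].append(res.subnetwork.n_edges)
        means = [np.mean(sizes[c]) for c in costs]  # descending cost order
        assert means == sorted(means)


class TestUniverseRestriction:
    def test_off_path_edge_only_hurts(self, toy_pathsets):
        """An edge on no retained path adds penalty but no connectivity."""
        pnet = toy_pathsets.network
        res = greedy_optimize(toy_pathsets, CFG)
        extra = [
            e for e in pnet.network.edges if e not in toy_pathsets.all_edges()
        ]
        base = objective(res.subnetwork, toy_pathsets, CFG)
        for e in extra:
            worse = objective(
                SubNetwork(edges=res.subnetwork.edges | {e}), toy_pathsets, CFG
            )
            assert worse.total < base.total
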