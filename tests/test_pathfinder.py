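"""Run-mode path validity, enumeration and k-best retention."""
from __future__ import annotations

import numpy as np
import pytest

from subnetx.pathfinder import (
    ConfigError,
    Path,
    RunConfig,
    enumerate_valid_paths,
    is_valid_path,
    k_best_paths,
    validate_config,
    _sort_key,
)

from conftest import make_pnet, make_path, random_pnet

UP = RunConfig(mode="upstream", cost=0.01)
DOWN = RunConfig(mode="downstream", cost=0.01)


class TestValidateConfig:
    def test_defaults_filled(self):
        cfg = validate_config(UP)
        assert cfg.max_path_length == 4
        assert cfg.k == 10

    @pytest.mark.parametrize("length", [1, 6, 0])
    def test_path_length_range_enforced(self, length):
        with pytest.raises(ConfigError, match=r"\[2, 5\]"):
            validate_config(RunConfig(mode="upstream", cost=0.0, max_path_length=length))

    @pytest.mark.parametrize("k", [4, 51])
    def test_k_range_enforced(self, k):
        with pytest.raises(ConfigError, match=r"\[5, 50\]"):
            validate_config(RunConfig(mode="downstream", cost=0.0, k=k))

    @pytest.mark.parametrize("k,length", [(5, 2), (50, 5)])
    def test_boundaries_inclusive(self, k, length):
        cfg = validate_config(
            RunConfig(mode="downstream", cost=0.0, k=k, max_path_length=length)
        )
        assert (cfg.k, cfg.max_path_length) == (k, length)

    def test_bad_mode_rejected(self):
        with pytest.raises(ConfigError, match="mode"):
            validate_config(RunConfig(mode="sideways", cost=0.0))

    def test_negative_cost_rejected(self):
        with pytest.raises(ConfigError, match="cost"):
            validate_config(RunConfig(mode="upstream", cost=-1.0))

    def test_upstream_needs_regulatory_types(self):
        with pytest.raises(ConfigError, match="regulatory"):
            validate_config(
                RunConfig(mode="upstream", cost=0.0, regulatory_types=frozenset())
            )


class TestIsValidPath:
    def test_upstream_apex_path(self, apex_pnet):
        # A <-pd- R -pd-> Y: against the flow up to R, then forward.
        path = make_path(apex_pnet, ("A", "R", "Y"), [0, 1], (False, True))
        assert is_valid_path(path, UP)

    def test_upstream_rejects_nonregulatory_first_edge(self):
        pnet = make_pnet([("A", "B", "pp", False), ("B", "Y", "pd", True)])
        path = make_path(pnet, ("A", "B", "Y"), [0, 1], (True, True))
        assert not is_valid_path(path, UP)

    def test_downstream_all_forward(self):
        pnet = make_pnet([("A", "B", "pd", True), ("B", "C", "met", True)])
        path = make_path(pnet, ("A", "B", "C"), [0, 1], (True, True))
        assert is_valid_path(path, DOWN)

    def test_downstream_rejects_reversed_directed_edge(self):
        pnet = make_pnet([("B", "A", "pd", True), ("B", "C", "met", True)])
        path = make_path(pnet, ("A", "B", "C"), [0, 1], (False, True))
        assert not is_valid_path(path, DOWN)

    def test_single_edge_path_invalid(self):
        pnet = make_pnet([("A", "B", "pd", True)])
        path = make_path(pnet, ("A", "B"), [0], (True,))
        assert not is_valid_path(path, DOWN)
        assert not is_valid_path(path, UP)

    def test_upstream_needs_nonempty_prefix_and_suffix(self):
        # Two forward pd edges: feasible split exists (undirected-free
        # prefix fails on a directed forward edge), so invalid upstream.
        pnet = make_pnet([("A", "B", "pd", True), ("B", "Y", "pd", True)])
        path = make_path(pnet, ("A", "B", "Y"), [0, 1], (True, True))
        assert not is_valid_path(path, UP)

    def test_undirected_edges_serve_either_segment(self):
        pnet = make_pnet([("A", "R", "srna", False), ("R", "Y", "pd", True)])
        path = make_path(pnet, ("A", "R", "Y"), [0, 1], (True, True))
        assert is_valid_path(path, UP)

    def test_repeated_node_invalid(self):
        pnet = make_pnet([("A", "B", "pd", True), ("B", "A", "met", True)])
        path = Path(
            nodes=("A", "B", "A"),
            edges=(pnet.network.edges[0], pnet.network.edges[1]),
            orientations=(True, True),
            probability=1.0,
        )
        assert not is_valid_path(path, DOWN)


class TestEnumerate:
    def test_triangle_downstream(self):
        pnet = make_pnet(
            [("A", "B", "pd", True), ("B", "C", "pd", True), ("A", "C", "pd", True)]
        )
        paths = enumerate_valid_paths(pnet, "A", ["C"], DOWN)
        # The only forward simple path with >= 2 edges is A -> B -> C.
        assert [p.nodes for p in paths] == [("A", "B", "C")]

    def test_upstream_apex_enumeration(self, apex_pnet):
        paths = enumerate_valid_paths(apex_pnet, "A", ["Y"], UP)
        assert ("A", "R", "Y") in [p.nodes for p in paths]
        for p in paths:
            assert is_valid_path(p, UP)

    def test_no_valid_path_gives_empty(self):
        pnet = make_pnet([("A", "B", "pd", True), ("C", "D", "pd", True)])
        assert enumerate_valid_paths(pnet, "A", ["C"], DOWN) == []

    def test_start_equals_target_excluded(self, apex_pnet):
        assert enumerate_valid_paths(apex_pnet, "A", ["A"], UP) == []

    def test_unknown_start_is_error(self, apex_pnet):
        with pytest.raises(ValueError, match="not in network"):
            enumerate_valid_paths(apex_pnet, "nope", ["Y"], UP)

    def test_length_bound_respected(self):
        chain = [(f"n{i}", f"n{i+1}", "pd", True) for i in range(6)]
        pnet = make_pnet(chain)
        cfg = RunConfig(mode="downstream", cost=0.0, max_path_length=3)
        paths = enumerate_valid_paths(pnet, "n0", ["n6"], cfg)
        assert paths == []  # n6 is 6 edges away
        paths = enumerate_valid_paths(pnet, "n0", ["n3"], cfg)
        assert [p.nodes for p in paths] == [("n0", "n1", "n2", "n3")]


class TestKBest:
    def test_zero_probability_path_retained(self):
        pnet = make_pnet(
            [("A", "B", "pd", True), ("B", "C", "pd", True)], probs={0: 0.0, 1: 0.9}
        )
        ps = k_best_paths(pnet, ["A", "C"], RunConfig(mode="downstream", cost=0.0, k=5))
        assert ps.by_pair[("A", "C")][0].probability == 0.0

    def test_k_larger_than_path_count_returns_all(self, apex_pnet):
        ps = k_best_paths(apex_pnet, ["A", "Y"], RunConfig(mode="upstream", cost=0.0, k=50))
        exhaustive = enumerate_valid_paths(apex_pnet, "A", ["Y"], UP)
        assert len(ps.by_pair[("A", "Y")]) == len(exhaustive)

    def test_absent_list_genes_dropped_with_warning(self, apex_pnet, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            ps = k_best_paths(apex_pnet, ["A", "Y", "ghost"], UP)
        assert any("absent" in r.message for r in caplog.records)
        assert ("A", "Y") in ps.by_pair

    def test_all_absent_is_error(self, apex_pnet):
        with pytest.raises(ValueError, match="no list genes"):
            k_best_paths(apex_pnet, ["ghost"], UP)

    @pytest.mark.parametrize("mode", ["upstream", "downstream"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_truncated_enumeration_on_random_graphs(self, mode, seed):
        """k-best retention equals sorting + truncating the exhaustive list."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        pnet = random_pnet(rng, n, int(rng.integers(n, 3 * n)))
        gene_list = list(
            rng.choice(sorted(pnet.network.nodes), size=min(4, n), replace=False)
        )
        cfg = RunConfig(mode=mode, cost=0.0, k=5, max_path_length=4)
        ps = k_best_paths(pnet, gene_list, cfg)
        for a in gene_list:
            exhaustive = enumerate_valid_paths(
                pnet, a, [g for g in gene_list if g != a], cfg
            )
            by_end = {}
            for p in exhaustive:
                by_end.setdefault(p.end, []).append(p)
            for end, expect in by_end.items():
                got = ps.by_pair.get((a, end), [])
                assert [(_sort_key(p)) for p in got] == [
                    _sort_key(p) for p in expect[: cfg.k]
                ]
            for pair, got in ps.by_pair.items():
                if pair[0] == a:
                    assert pair[1] in by_end or not got

    @pytest.mark.parametrize("seed", range(5))
    def test_every_retained_path_is_valid(self, seed):
        rng = np.random.default_rng(100 + seed)
        pnet = random_pnet(rng, 8, 20)
        genes = sorted(pnet.network.nodes)[:4]
        for mode in ("upstream", "downstream"):
            cfg = validate_config(RunConfig(mode=mode, cost=0.0, k=5))
            ps = k_best_paths(pnet, genes, cfg)
            for (a, y), paths in ps.by_pair.items():
                for p in paths:
                    assert p.start == a and p.end == y
                    assert is_valid_path(p, cfg)
                    assert len(set(p.nodes)) == len(p.nodes)
                    assert 2 <= p.length <= cfg.max_path_length

    def test_start_scope_pools_k_over_end_genes(self, apex_pnet):
        cfg = RunConfig(mode="upstream", cost=0.0, k=5, k_scope="start")
        ps = k_best_paths(apex_pnet, ["A", "Y"], cfg)
        assert sum(len(v) for (a, _), v in ps.by_pair.items() if a == "A") <= 5

    def test_deterministic_ordering(self, apex_pnet):
        ps1 = k_best_paths(apex_pnet, ["A", "Y"], UP)
        ps2 = k_best_paths(apex_pnet, ["A", "Y"], UP)
        assert ps1.by_pair == ps2.by_pair
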