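"""Clique enrichment, module assembly, ASPL and core extraction."""

import math
from math import comb

import numpy as np
import pytest

from susmod import (
    SusceptibilityModule,
    build_susceptibility_module,
    compute_average_shortest_path_lengths,
    enrich_cliques,
    extract_core_module,
    fisher_clique_enrichment,
)
from susmod.modules import EmptyModuleError, module_summary

from conftest import make_network


def exact_tail(a, N, K, s):
    """Independent one-sided Fisher p: exact hypergeometric tail by
    integer binomial coefficients."""
    denom = comb(N, s)
    return sum(comb(K, j) * comb(N - K, s - j) for j in range(a, min(K, s) + 1)) / denom


UNIVERSE_100 = {f"u{i:03d}" for i in range(100)}


class TestFisher:
    def test_fully_de_clique(self):
        universe = set(UNIVERSE_100)
        de = {f"u{i:03d}" for i in range(10)}
        clique = ["u000", "u001", "u002", "u003"]
        rec = fisher_clique_enrichment(clique, de, universe)
        assert rec.a == 4 and rec.s == 4 and rec.K == 10 and rec.N == 100
        assert rec.p_fisher == pytest.approx(210 / 3_921_225, rel=1e-12)
        assert rec.enriched

    def test_no_de_members_gives_p_one(self):
        de = {f"u{i:03d}" for i in range(10)}
        rec = fisher_clique_enrichment(["u050", "u051"], de, set(UNIVERSE_100))
        assert rec.p_fisher == pytest.approx(1.0)
        assert not rec.enriched

    def test_half_de_universe_two_of_four(self):
        de = {f"u{i:03d}" for i in range(50)}
        clique = ["u000", "u001", "u060", "u061"]
        rec = fisher_clique_enrichment(clique, de, set(UNIVERSE_100))
        assert rec.p_fisher == pytest.approx(0.6913464542330522, rel=1e-9)
        assert not rec.enriched

    def test_clique_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            fisher_clique_enrichment(["x", "y"], set(), {"x"})

    def test_matches_exact_tail_on_small_grid(self):
        for N in (10, 25, 60):
            universe = {f"u{i}" for i in range(N)}
            for K in range(0, N + 1, max(1, N // 5)):
                de = {f"u{i}" for i in range(K)}
                for s in (2, 3, 5):
                    if s > N:
                        continue
                    for a in range(0, min(s, K) + 1):
                        clique = [f"u{i}" for i in range(a)] + [
                            f"u{K + i}" for i in range(s - a)
                        ]
                        if K + (s - a) > N:
                            continue
                        rec = fisher_clique_enrichment(clique, de, universe)
                        assert rec.p_fisher == pytest.approx(
                            exact_tail(a, N, K, s), rel=1e-9, abs=1e-300
                        )


class TestModuleAssembly:
    def _records(self, cliques, de, universe, alpha=0.05):
        return enrich_cliques(cliques, de, universe, alpha)

    def test_union_with_induced_edges(self):
        net = make_network(
            [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("B", "D")]
        )
        universe = {f"u{i}" for i in range(96)} | {"A", "B", "C", "D"}
        de = {"A", "B", "C", "D"}
        records = self._records([("A", "B", "C"), ("C", "D")], de, universe)
        assert all(r.enriched for r in records)
        mod = build_susceptibility_module(records, net, "toy")
        assert mod.genes == {"A", "B", "C", "D"}
        # induced edges include B-D although it is in neither clique
        assert mod.edges == {
            ("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")
        }

    def test_non_de_clique_neighbours_are_included(self):
        net = make_network([("A", "B")])
        universe = {f"u{i}" for i in range(40)} | {"A", "B"}
        de = {"A"}
        records = self._records([("A", "B")], de, universe)
        mod = build_susceptibility_module(records, net, "toy")
        if records[0].enriched:
            assert "B" in mod.genes  # neighbour joins despite not being DE
            assert mod.n_de_in_module == 1

    def test_no_enriched_cliques_yields_empty_module(self):
        net = make_network([("A", "B")])
        universe = {f"u{i}" for i in range(100)} | {"A", "B"}
        records = self._records([("A", "B")], set(), universe)
        mod = build_susceptibility_module(records, net, "toy")
        assert mod.empty and mod.genes == frozenset()

    def test_module_gene_count_at_least_de_in_enriched_cliques(self):
        net = make_network([("A", "B"), ("B", "C"), ("A", "C")])
        universe = {f"u{i}" for i in range(60)} | {"A", "B", "C"}
        de = {"A", "B"}
        records = self._records([("A", "B", "C")], de, universe)
        mod = build_susceptibility_module(records, net, "toy")
        de_in_cliques = set().union(
            *(r.de_members for r in records if r.enriched)
        ) if any(r.enriched for r in records) else set()
        assert len(mod.genes) >= len(de_in_cliques)

    def test_bh_across_cliques_is_more_conservative(self):
        net = make_network([(f"a{i}", f"b{i}") for i in range(20)])
        universe = {f"u{i}" for i in range(400)} | set(net.nodes)
        de = {f"a{i}" for i in range(20)} | {f"b{i}" for i in range(3)}
        cliques = [(f"a{i}", f"b{i}") for i in range(20)]
        raw = enrich_cliques(cliques, de, universe, 0.05)
        adj = enrich_cliques(cliques, de, universe, 0.05, adjust=True)
        n_raw = sum(r.enriched for r in raw)
        n_adj = sum(r.enriched for r in adj)
        assert n_adj <= n_raw


def module_from_edges(edges, genes=None):
    genes = genes or sorted({g for e in edges for g in e})
    return SusceptibilityModule(
        disease="toy",
        genes=frozenset(genes),
        edges=frozenset(tuple(sorted(e)) for e in edges),
        contributing_cliques=(),
        n_de_in_module=0,
    )


class TestASPL:
    def test_path_graph(self):
        mod = module_from_edges([("A", "B"), ("B", "C")])
        aspl = compute_average_shortest_path_lengths(mod)
        assert aspl["A"] == pytest.approx(1.5)
        assert aspl["B"] == pytest.approx(1.0)

    def test_star_graph(self):
        edges = [("H", f"L{i}") for i in range(4)]
        aspl = compute_average_shortest_path_lengths(module_from_edges(edges))
        assert aspl["H"] == pytest.approx(1.0)
        for i in range(4):
            assert aspl[f"L{i}"] == pytest.approx(1.75)

    def test_disconnected_pairs_average_over_reachable_only(self):
        mod = module_from_edges([("A", "B"), ("C", "D")])
        aspl = compute_average_shortest_path_lengths(mod)
        assert all(aspl[g] == pytest.approx(1.0) for g in "ABCD")

    def test_isolated_gene_is_nan(self):
        mod = module_from_edges([("A", "B")], genes=["A", "B", "Z"])
        aspl = compute_average_shortest_path_lengths(mod)
        assert math.isnan(aspl["Z"])

    def test_matches_bfs_matrix_oracle(self):
        import networkx as nx
        from scipy.sparse.csgraph import shortest_path

        g = nx.gnp_random_graph(15, 0.25, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        mod = module_from_edges(list(g.edges), genes=sorted(g.nodes))
        aspl = compute_average_shortest_path_lengths(mod)
        nodes = sorted(g.nodes)
        dist = shortest_path(nx.to_scipy_sparse_array(g, nodelist=nodes))
        for i, gene in enumerate(nodes):
            finite = [d for j, d in enumerate(dist[i]) if j != i and np.isfinite(d)]
            expect = float(np.mean(finite)) if finite else math.nan
            if math.isnan(expect):
                assert math.isnan(aspl[gene])
            else:
                assert aspl[gene] == pytest.approx(expect)

    def test_empty_module_rejected(self):
        mod = SusceptibilityModule(
            disease="d", genes=frozenset(), edges=frozenset(),
            contributing_cliques=(), n_de_in_module=0, empty=True,
        )
        with pytest.raises(EmptyModuleError):
            compute_average_shortest_path_lengths(mod)

    def test_full_network_variant(self):
        # A-B inside the module, connected through external hub X
        net = make_network([("A", "X"), ("X", "B"), ("A", "B")])
        mod = module_from_edges([("A", "B")])
        within = compute_average_shortest_path_lengths(mod)
        full = compute_average_shortest_path_lengths(
            mod, network=net, on_full_network=True
        )
        assert within["A"] == full["A"] == pytest.approx(1.0)


class TestCoreExtraction:
    def _module_and_aspl(self, n=20):
        genes = [f"g{i:02d}" for i in range(n)]
        edges = [(genes[i], genes[i + 1]) for i in range(n - 1)]
        mod = module_from_edges(edges, genes)
        aspl = {g: float(i + 1) for i, g in enumerate(genes)}
        return mod, aspl

    def test_ten_percent_of_twenty_is_two(self):
        mod, aspl = self._module_and_aspl(20)
        core = extract_core_module(mod, aspl, 0.10)
        assert core.genes == {"g00", "g01"}

    def test_fraction_one_takes_everything(self):
        mod, aspl = self._module_and_aspl(20)
        core = extract_core_module(mod, aspl, 1.0)
        assert core.genes == mod.genes

    def test_ties_broken_lexicographically(self):
        mod, aspl = self._module_and_aspl(20)
        aspl = dict.fromkeys(aspl, 1.0)
        core = extract_core_module(mod, aspl, 0.10)
        assert core.genes == {"g00", "g01"}

    def test_ceil_rounding(self):
        mod, aspl = self._module_and_aspl(11)
        core = extract_core_module(mod, aspl, 0.10)
        assert core.size == 2  # ceil(1.1)

    def test_nestedness_under_stricter_fraction(self):
        mod, aspl = self._module_and_aspl(20)
        inner = extract_core_module(mod, aspl, 0.10)
        outer = extract_core_module(mod, aspl, 0.30)
        assert inner.genes <= outer.genes <= mod.genes

    def test_fraction_out_of_range_rejected(self):
        mod, aspl = self._module_and_aspl(5)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                extract_core_module(mod, aspl, bad)

    def test_all_undefined_aspl_rejected(self):
        mod, _ = self._module_and_aspl(5)
        nan_aspl = dict.fromkeys(mod.genes, math.nan)
        with pytest.raises(ValueError, match="undefined"):
            extract_core_module(mod, nan_aspl, 0.5)

    def test_summary_row_is_consistent(self):
        mod, aspl = self._module_and_aspl(20)
        core = extract_core_module(mod, aspl, 0.10)
        row = module_summary(mod, core)
        assert row["genes_in_sum"] == 20
        assert row["genes_in_core"] == math.ceil(0.10 * 20)
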