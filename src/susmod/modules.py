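"""Susceptibility-module discovery.

The core algorithm: every maximal clique of the filtered interaction
network is tested for over-representation of differentially expressed
genes with a one-sided Fisher exact (hypergeometric tail) test; the
union of enriched cliques, mapped back onto the network with each gene
represented once, is the susceptibility module (SuM).  Within a module,
genes are ranked by average shortest path length (ASPL) and the lowest
decile (by default) forms the core module — the most interconnected
genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import PPINetwork


class EmptyModuleError(ValueError):
    """Raised when a downstream step receives an empty module."""


@dataclass
class CliqueEnrichmentRecord:
    """Fisher enrichment of one clique for DE genes.

    ``a`` DE genes among the ``s`` clique members, against ``K`` DE genes
    in the ``N``-gene universe.  ``p_fisher`` is the one-sided tail
    P(X >= a), X ~ Hypergeometric(N, K, s).
    """

    clique: tuple[str, ...]
    a: int
    s: int
    K: int
    N: int
    p_fisher: float
    enriched: bool
    de_members: frozenset[str] = field(default_factory=frozenset)


def fisher_clique_enrichment(
    clique: Sequence[str],
    de_genes: set[str],
    universe: set[str],
    alpha_clique: float = 0.05,
) -> CliqueEnrichmentRecord:
    """One-sided Fisher exact test for DE enrichment of a single clique.

    Enrichment direction only: p = P(X >= a) for X hypergeometric with
    population ``N = |universe|``, successes ``K = |de_genes ∩ universe|``
    and draws ``s = |clique|``.  ``enriched`` is strict: p < alpha.
    """
    cset = set(clique)
    if not cset <= universe:
        raise ValueError(
            f"clique contains genes outside the universe: "
            f"{sorted(cset - universe)[:5]}"
        )
    de_in_universe = de_genes & universe
    N = len(universe)
    K = len(de_in_universe)
    s = len(cset)
    de_members = frozenset(cset & de_in_universe)
    a = len(de_members)
    p = float(hypergeom.sf(a - 1, N, K, s))
    return CliqueEnrichmentRecord(
        clique=tuple(sorted(cset)),
        a=a,
        s=s,
        K=K,
        N=N,
        p_fisher=p,
        enriched=bool(p < alpha_clique),
        de_members=de_members,
    )


def enrich_cliques(
    cliques: Iterable[Sequence[str]],
    de_genes: set[str],
    universe: set[str],
    alpha_clique: float = 0.05,
    adjust: bool = False,
) -> list[CliqueEnrichmentRecord]:
    """Test every clique; optionally BH-adjust p-values across cliques.

    The default is no across-clique correction (each clique judged at
    raw p < alpha); ``adjust=True`` replaces the enrichment call with
    BH-adjusted p < alpha.
    """
    records = [
        fisher_clique_enrichment(c, de_genes, universe, alpha_clique)
        for c in cliques
    ]
    if adjust and records:
        padj = multipletests(
            [r.p_fisher for r in records], method="fdr_bh"
        )[1]
        for r, q in zip(records, padj):
            r.enriched = bool(q < alpha_clique)
    return records


@dataclass
class SusceptibilityModule:
    """Union of enriched cliques mapped onto the network.

    ``genes`` contains both DE genes and their non-DE clique neighbours;
    ``edges`` is the full induced subgraph of the parent network over
    ``genes`` (a superset of the within-clique edges).
    """

    disease: str
    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    contributing_cliques: tuple[tuple[str, ...], ...]
    n_de_in_module: int
    empty: bool = False

    def subgraph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g


def build_susceptibility_module(
    records: Iterable[CliqueEnrichmentRecord],
    network: PPINetwork,
    disease: str = "",
) -> SusceptibilityModule:
    """Assemble the susceptibility module from enriched cliques.

    Module genes are the union over enriched records (each gene once);
    module edges are *all* network edges with both endpoints inside the
    module, not only within-clique edges.  With no enriched clique an
    empty module is returned with ``empty=True`` — downstream steps
    refuse it.
    """
    enriched = [r for r in records if r.enriched]
    genes: set[str] = set()
    de_members: set[str] = set()
    for r in enriched:
        genes |= set(r.clique)
        de_members |= r.de_members
    if not genes:
        return SusceptibilityModule(
            disease=disease,
            genes=frozenset(),
            edges=frozenset(),
            contributing_cliques=(),
            n_de_in_module=0,
            empty=True,
        )
    sub = network.induced_subgraph(genes)
    edges = frozenset(
        (u, v) if u <= v else (v, u) for u, v in sub.edges
    )
    return SusceptibilityModule(
        disease=disease,
        genes=frozenset(genes),
        edges=edges,
        contributing_cliques=tuple(sorted(r.clique for r in enriched)),
        n_de_in_module=len(de_members),
    )


def compute_average_shortest_path_lengths(
    module: SusceptibilityModule,
    network: PPINetwork | None = None,
    on_full_network: bool = False,
) -> dict[str, float]:
    """Per-gene average shortest path length (ASPL).

    For each module gene g, ASPL(g) is the mean unweighted shortest-path
    distance from g to every *reachable* other gene.  By default paths
    are taken within the module's induced subgraph; with
    ``on_full_network=True`` (requires ``network``) distances are
    measured on the whole interaction network but averaged over
    reachable module genes only, for sensitivity analysis.  Genes with
    no reachable partner get ``nan`` and are ineligible for the core.
    """
    if module.empty or not module.genes:
        raise EmptyModuleError("cannot compute ASPL of an empty module")
    if on_full_network:
        if network is None:
            raise ValueError("on_full_network=True requires the network")
        g = network.graph
    else:
        g = module.subgraph()
    aspl: dict[str, float] = {}
    members = set(module.genes)
    for gene in module.genes:
        if gene not in g:
            aspl[gene] = math.nan
            continue
        dist = nx.single_source_shortest_path_length(g, gene)
        reach = [d for other, d in dist.items() if other in members and other != gene]
        aspl[gene] = float(np.mean(reach)) if reach else math.nan
    return aspl


@dataclass
class CoreModule:
    """The most interconnected fraction of a susceptibility module."""

    disease: str
    genes: frozenset[str]
    aspl: dict[str, float]
    fraction: float

    @property
    def size(self) -> int:
        return len(self.genes)


def extract_core_module(
    module: SusceptibilityModule,
    aspl: Mapping[str, float],
    fraction: float = 0.10,
) -> CoreModule:
    """Take the ``fraction`` of module genes with the lowest ASPL.

    The target size is ceil(fraction * |module genes|).  Eligible genes
    (finite ASPL) are ranked by (ASPL ascending, gene id ascending) for
    a deterministic tie-break; if fewer genes are eligible than the
    target, all eligible genes are returned.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if module.empty or not module.genes:
        raise EmptyModuleError("cannot extract core of an empty module")
    eligible = sorted(
        (g for g in module.genes if math.isfinite(aspl.get(g, math.nan))),
        key=lambda g: (aspl[g], g),
    )
    if not eligible:
        raise ValueError("all module genes have undefined ASPL")
    n_core = math.ceil(fraction * len(module.genes))
    chosen = eligible[:n_core]
    return CoreModule(
        disease=module.disease,
        genes=frozenset(chosen),
        aspl={g: float(aspl[g]) for g in chosen},
        fraction=fraction,
    )


def module_summary(
    module: SusceptibilityModule, core: CoreModule | None = None
) -> dict:
    """One summary row per disease: sizes and DE content."""
    row = {
        "disease": module.disease,
        "genes_in_sum": len(module.genes),
        "de_genes_in_sum": module.n_de_in_module,
        "n_cliques": len(module.contributing_cliques),
    }
    if core is not None:
        row["genes_in_core"] = core.size
        row["core_fraction"] = core.fraction
    return row


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_edge_list(
    edges: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(edges):
            fh.write(f"{u}\t{v}\n")
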