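import networkx as nx
import numpy as np
import pandas as pd
import pytest

from susmod import ExpressionMatrix, PPINetwork


def make_network(edges, confidence=1.0):
    """Small PPI network from a list of (u, v) or (u, v, conf) tuples."""
    g = nx.Graph()
    for e in edges:
        u, v = e[0], e[1]
        c = e[2] if len(e) > 2 else confidence
        g.add_edge(u, v, confidence=c)
    return PPINetwork(graph=g, min_confidence=0.0, source="test")


def make_expression(case_rows, control_rows, genes=None):
    """Expression matrix from per-gene case/control value lists."""
    case = np.asarray(case_rows, dtype=float)
    ctrl = np.asarray(control_rows, dtype=float)
    n_genes = case.shape[0]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    case_ids = [f"case{j}" for j in range(case.shape[1])]
    ctrl_ids = [f"ctrl{j}" for j in range(ctrl.shape[1])]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=genes, columns=case_ids + ctrl_ids
    )
    groups = pd.Series(
        ["case"] * len(case_ids) + ["control"] * len(ctrl_ids),
        index=case_ids + ctrl_ids,
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def triangle_net():
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


def brute_force_maximal_cliques(graph: nx.Graph, min_size: int = 2):
    """Exhaustive-subset maximal-clique oracle for graphs with <= ~16 nodes.

    Tests every vertex subset for clique-ness, then filters out subsets
    properly contained in another clique.  Independent of the
    Bron-Kerbosch route used by the implementation.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        if u == v:
            continue
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    cliques = []
    for s in range(1, 1 << n):
        ok = True
        t = s
        while t:
            i = (t & -t).bit_length() - 1
            if s & ~(adj[i] | (1 << i)):
                ok = False
                break
            t &= t - 1
        if ok:
            cliques.append(s)
    maximal = [
        s
        for s in cliques
        if not any(s != u and (s & u) == s for u in cliques)
    ]
    out = set()
    for s in maximal:
        members = tuple(nodes[i] for i in range(n) if s >> i & 1)
        if len(members) >= min_size:
            out.add(frozenset(members))
    return out
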