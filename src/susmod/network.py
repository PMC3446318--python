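"""Protein-protein interaction network loading and clique enumeration.

The network is the universe for every downstream statistic: genes are
observable in a susceptibility module only if they carry at least one
retained interaction.  Interactions come as a STRING-style edge list
(gene A, gene B, combined confidence score) and are filtered at a
confidence threshold (default 0.7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx


class NetworkFormatError(ValueError):
    """Raised when the interaction file cannot be parsed."""


@dataclass
class PPINetwork:
    """Undirected, confidence-filtered protein-protein interaction network.

    Parameters
    ----------
    graph
        Undirected :class:`networkx.Graph`; each edge carries a
        ``confidence`` attribute in [0, 1].  Only nodes with at least one
        retained edge are present (isolated genes are not part of the
        universe).
    min_confidence
        The confidence threshold that was applied.
    source
        Free-text label for provenance (file name or ``"simulated"``).
    """

    graph: nx.Graph
    min_confidence: float = 0.0
    source: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d.get("confidence", 1.0)

    def induced_subgraph(self, genes: Iterable[str]) -> nx.Graph:
        """Subgraph induced by ``genes`` (unknown genes ignored)."""
        keep = [g for g in genes if g in self.graph]
        return self.graph.subgraph(keep).copy()

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
        for _, _, c in self.edges():
            if c < self.min_confidence:
                raise ValueError("edge below applied confidence threshold")
        for n in self.graph.nodes:
            if self.graph.degree(n) == 0:
                raise ValueError(f"isolated node {n!r} retained")


def _parse_edge_rows(path: str | Path) -> list[tuple[int, str, str, float]]:
    rows: list[tuple[int, str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"line {lineno}: expected at least 3 columns, got {len(parts)}"
                )
            try:
                score = float(parts[2])
            except ValueError:
                # a non-numeric score field on the first data row is a header
                if not rows and lineno <= 1:
                    continue
                raise NetworkFormatError(
                    f"line {lineno}: score field {parts[2]!r} is not numeric"
                ) from None
            if not math.isfinite(score) or score < 0:
                raise NetworkFormatError(
                    f"line {lineno}: score {score} out of range"
                )
            rows.append((lineno, parts[0], parts[1], score))
    return rows


def load_ppi_network(
    path: str | Path, min_confidence: float = 0.7
) -> PPINetwork:
    """Load a STRING-dialect edge list and filter by confidence.

    The score column is auto-detected: if any score exceeds 1 the file is
    taken to use STRING's integer 0-1000 scale and all scores are divided
    by 1000, so a threshold of 0.7 is equivalent to 700.  The filter is
    inclusive (score >= ``min_confidence`` is kept).  Duplicate pairs
    (including reversed order) are merged keeping the maximum score;
    self-loops are dropped; genes without any retained edge are excluded.

    Raises
    ------
    NetworkFormatError
        On a malformed row (with its line number).
    ValueError
        If no edge survives the confidence filter (empty universe).
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must be in [0, 1]")
    rows = _parse_edge_rows(path)
    scale = 1000.0 if any(r[3] > 1.0 for r in rows) else 1.0

    best: dict[tuple[str, str], float] = {}
    for lineno, a, b, score in rows:
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        conf = score / scale
        if conf > best.get(key, -1.0):
            best[key] = conf

    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf >= min_confidence:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no interaction passed confidence >= {min_confidence}: "
            "the gene universe would be empty"
        )
    return PPINetwork(graph=g, min_confidence=min_confidence, source=str(path))


def enumerate_maximal_cliques(
    network: PPINetwork, min_size: int = 2
) -> list[tuple[str, ...]]:
    """Enumerate all maximal cliques of size >= ``min_size``.

    Uses Bron-Kerbosch with pivoting (networkx ``find_cliques``).  Output
    is deterministic: each clique's members are sorted, and cliques are
    sorted lexicographically.  With ``min_size=2`` and a network without
    isolated nodes, every edge belongs to at least one returned clique.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    cliques = [
        tuple(sorted(c))
        for c in nx.find_cliques(network.graph)
        if len(c) >= min_size
    ]
    cliques.sort()
    return cliques


def write_cliques(cliques: Sequence[Sequence[str]], path: str | Path) -> None:
    """Write one clique per line as tab-joined sorted gene ids."""
    with open(path, "w") as fh:
        for c in cliques:
            fh.write("\t".join(sorted(c)) + "\n")


def read_cliques(path: str | Path) -> list[tuple[str, ...]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(tuple(line.split("\t")))
    return out
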