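"""GWAS-gene enrichment of modules by permutation, and module-overlap
statistics.

The permutation null replaces the whole GWAS gene set with a uniformly
drawn set of the same size from the network universe; enrichment is the
observed overlap with a module divided by the mean permuted overlap,
with an empirical p-value.  Jointly redrawing the set is exactly the
hypergeometric null, so expected counts are analytically checkable.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)


@dataclass
class GWASCatalog:
    """Disease -> GWAS gene set mapping from a published catalog."""

    diseases: dict[str, frozenset[str]]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.diseases.values():
            out |= s
        return out

    def pleiotropy_counts(
        self, exclude_diseases: Iterable[str] = ()
    ) -> Counter:
        """Number of (non-excluded) diseases listing each gene."""
        excl = set(exclude_diseases)
        counts: Counter = Counter()
        for disease, genes in self.diseases.items():
            if disease in excl:
                continue
            counts.update(genes)
        return counts

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GWASCatalog":
        """Two-column TSV: disease label, gene id (one pair per line)."""
        diseases: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"bad catalog line: {line!r}")
                diseases.setdefault(parts[0], set()).add(parts[1])
        return cls({d: frozenset(g) for d, g in diseases.items()})

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GWASCatalog":
        """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
        diseases: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                diseases[parts[0]] = frozenset(g for g in parts[2:] if g)
        return cls(diseases)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for disease in sorted(self.diseases):
                for gene in sorted(self.diseases[disease]):
                    fh.write(f"{disease}\t{gene}\n")


@dataclass
class PermutationEnrichmentResult:
    """Observed vs permuted overlap of a gene set with a module."""

    observed: int
    expected: float
    fold: float
    p_empirical: float
    n_perm: int
    seed: int
    n_query: int
    n_target: int
    n_universe: int
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_query": self.n_query,
            "n_target": self.n_target,
            "n_universe": self.n_universe,
            "n_dropped": self.n_dropped,
        }


def _permuted_overlaps(
    rng: np.random.Generator,
    target_mask: np.ndarray,
    q: int,
    n_perm: int,
    chunk_elems: int = 4_000_000,
) -> np.ndarray:
    """Overlap counts for ``n_perm`` uniform q-subsets of the universe.

    Each permutation draws the q smallest of n iid uniform keys, i.e. a
    uniform subset without replacement.  Chunked to bound memory.
    """
    n = target_mask.size
    if q == n:
        return np.full(n_perm, int(target_mask.sum()), dtype=np.int64)
    counts = np.empty(n_perm, dtype=np.int64)
    rows_per_chunk = max(1, chunk_elems // n)
    done = 0
    while done < n_perm:
        rows = min(rows_per_chunk, n_perm - done)
        keys = rng.random((rows, n))
        idx = np.argpartition(keys, q, axis=1)[:, :q]
        counts[done : done + rows] = target_mask[idx].sum(axis=1)
        done += rows
    return counts


def permutation_set_enrichment(
    target: Iterable[str],
    query: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> PermutationEnrichmentResult:
    """Permutation test for over-representation of ``query`` in ``target``.

    ``target`` (module genes) must lie inside the universe; query genes
    outside the universe are dropped (their count is logged and
    reported).  Each permutation redraws |query| genes uniformly without
    replacement from the universe.  The empirical p-value uses the
    add-one estimator (r+1)/(n_perm+1), so it is never exactly zero: a
    result with no exceedance reads "< 1/n_perm".
    """
    universe_list = sorted(set(universe))
    n = len(universe_list)
    target_set = set(target)
    if not target_set <= set(universe_list):
        raise ValueError("target genes must be a subset of the universe")
    query_set = set(query)
    query_in = query_set & set(universe_list)
    n_dropped = len(query_set) - len(query_in)
    if n_dropped:
        logger.info(
            "dropped %d query gene(s) absent from the universe", n_dropped
        )
    if not query_in:
        raise ValueError("query set is empty after universe filtering")
    q = len(query_in)
    if q > n:
        raise ValueError("query larger than universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    mask = np.fromiter(
        (g in target_set for g in universe_list), dtype=bool, count=n
    )
    observed = len(query_in & target_set)
    rng = np.random.default_rng(seed)
    counts = _permuted_overlaps(rng, mask, q, n_perm)
    expected = float(counts.mean())
    p = (int((counts >= observed).sum()) + 1) / (n_perm + 1)
    fold = observed / expected if expected > 0 else math.nan
    return PermutationEnrichmentResult(
        observed=observed,
        expected=expected,
        fold=fold,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
        n_query=q,
        n_target=len(target_set),
        n_universe=n,
        n_dropped=n_dropped,
    )


def pooled_permutation_enrichment(
    pairs: Sequence[tuple[Iterable[str], Iterable[str]]],
    universe: Iterable[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> PermutationEnrichmentResult:
    """Totals-row permutation test over several (target, query) pairs.

    For a multi-disease analysis the observed overlaps are summed across
    diseases and, within each permutation, every disease's query set is
    independently redrawn and its overlap added to the permuted total —
    the null for the "Total" row of a per-disease summary table.
    """
    if not pairs:
        raise ValueError("no (target, query) pairs given")
    universe_list = sorted(set(universe))
    uni_set = set(universe_list)
    n = len(universe_list)
    rng = np.random.default_rng(seed)
    total_counts = np.zeros(n_perm, dtype=np.int64)
    total_observed = 0
    total_q = 0
    for target, query in pairs:
        target_set = set(target)
        if not target_set <= uni_set:
            raise ValueError("target genes must be a subset of the universe")
        query_in = set(query) & uni_set
        if not query_in:
            raise ValueError("a query set is empty after universe filtering")
        mask = np.fromiter(
            (g in target_set for g in universe_list), dtype=bool, count=n
        )
        total_observed += len(query_in & target_set)
        total_q += len(query_in)
        total_counts += _permuted_overlaps(rng, mask, len(query_in), n_perm)
    expected = float(total_counts.mean())
    p = (int((total_counts >= total_observed).sum()) + 1) / (n_perm + 1)
    fold = total_observed / expected if expected > 0 else math.nan
    return PermutationEnrichmentResult(
        observed=total_observed,
        expected=expected,
        fold=fold,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
        n_query=total_q,
        n_target=-1,
        n_universe=n,
    )


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def jaccard_matrix(
    named_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Pairwise Jaccard similarity matrix (heatmap-ready)."""
    names = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    mat = pd.DataFrame(
        [[jaccard_index(sets[i], sets[j]) for j in names] for i in names],
        index=names,
        columns=names,
    )
    return mat


def replication_chi_square(
    a: Iterable[str], b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    membership table of two gene sets over a common universe.

    Used to ask whether a module replicates across independent data
    sets: a large statistic means membership in ``a`` and ``b`` is far
    from independent.
    """
    uni = set(universe)
    sa, sb = set(a) & uni, set(b) & uni
    if not sa <= uni or not sb <= uni:
        raise ValueError("sets must be subsets of the universe")
    if not sa or not sb or sa == uni or sb == uni:
        raise ValueError("degenerate 2x2 table (empty or full set)")
    n11 = len(sa & sb)
    n10 = len(sa - sb)
    n01 = len(sb - sa)
    n00 = len(uni) - n11 - n10 - n01
    stat, p, _, _ = chi2_contingency(
        [[n11, n10], [n01, n00]], correction=False
    )
    return float(stat), float(p)


def stratify_by_pleiotropy(
    catalog: GWASCatalog,
    min_diseases: int,
    exclude_diseases: Iterable[str] = (),
) -> set[str]:
    """Genes listed for at least ``min_diseases`` non-excluded diseases.

    "Associated with more than one disease" corresponds to
    ``min_diseases=2``, "more than four" to ``min_diseases=5``.
    Excluded diseases are removed from the catalog before counting.
    """
    if min_diseases < 1:
        raise ValueError("min_diseases must be >= 1")
    counts = catalog.pleiotropy_counts(exclude_diseases)
    return {g for g, c in counts.items() if c >= min_diseases}


def union_of_sets(sets: Iterable[Iterable[str]]) -> set[str]:
    """Plain union, e.g. the union of core modules across diseases."""
    out: set[str] = set()
    for s in sets:
        out |= set(s)
    return out


def aggregate_observed_expected(table: pd.DataFrame) -> dict:
    """Column sums and fold ratios for a per-disease summary table.

    Expects columns ``observed_sum``, ``expected_sum``,
    ``observed_core``, ``expected_core`` (one row per disease).  Fold is
    the totals ratio observed/expected.
    """
    out = {}
    for col in ("observed_sum", "expected_sum", "observed_core", "expected_core"):
        if col in table.columns:
            out[f"total_{col}"] = float(table[col].sum())
    if {"observed_sum", "expected_sum"} <= set(table.columns):
        out["fold_sum"] = out["total_observed_sum"] / out["total_expected_sum"]
    if {"observed_core", "expected_core"} <= set(table.columns):
        out["fold_core"] = out["total_observed_core"] / out["total_expected_core"]
    return out
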