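"""Synthetic data with planted structure for end-to-end validation.

The generator emulates the statistical structure the discovery method
assumes: an Erdős–Rényi background interaction network with planted
dense modules, case/control expression in which mean-shifted DE genes
concentrate inside the planted modules, a GWAS catalog whose gene lists
overlap the planted modules, and intragenic SNP association p-values
enriched for significance inside the planted core genes.  Everything is
seed-deterministic; a single call materialises a complete demo data set
in the exact file formats the analysis modules read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, ExpressionMatrix
from .gwas import GWASCatalog
from .network import PPINetwork
from .snps import INTERVAL_COLUMNS, SNP_COLUMNS

GENE_LENGTH = 1000  # bp per synthetic gene
GENE_GAP = 100  # bp between consecutive genes


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``planted_modules`` is a list of ``(size, density)`` or
    ``(size, density, offset)`` tuples; modules without an explicit
    offset are placed consecutively from gene 0, and an explicit offset
    allows nesting (a dense core inside a larger module).  SNP p-values
    inside the genes of the *densest* planted module have their
    probability of falling below ``snp_alpha`` multiplied by
    ``snp_sig_enrichment``.
    """

    n_genes: int = 500
    edge_prob: float = 0.01
    planted_modules: Sequence[tuple] = ((40, 0.15, 0), (10, 1.0, 0))
    de_effect: float = 2.0
    noise_sd: float = 1.0
    n_case: int = 10
    n_control: int = 10
    frac_de_in_planted: float = 0.8
    frac_de_background: float = 0.0
    n_gwas_genes: int = 15
    gwas_overlap_frac: float = 0.6
    n_diseases: int = 1
    n_snps_per_gene: int = 100
    snp_sig_enrichment: float = 5.0
    snp_alpha: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_prob", "frac_de_in_planted", "frac_de_background",
                     "gwas_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1 or self.n_snps_per_gene < 0:
            raise ValueError("sizes must be positive")
        for mod in self.planted_modules:
            size, density = mod[0], mod[1]
            offset = mod[2] if len(mod) > 2 else 0
            if size < 1 or offset < 0 or offset + size > self.n_genes:
                raise ValueError("planted module does not fit in the genome")
            if not 0.0 < density <= 1.0:
                raise ValueError("planted density must be in (0, 1]")
        if self.snp_sig_enrichment < 1.0:
            raise ValueError("snp_sig_enrichment must be >= 1")
        if self.snp_sig_enrichment * self.snp_alpha > 1.0:
            raise ValueError("snp_sig_enrichment * snp_alpha exceeds 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def module_members(self) -> list[list[str]]:
        """Gene ids of each planted module (explicit or packed offsets)."""
        genes = self.gene_ids()
        members = []
        cursor = 0
        for mod in self.planted_modules:
            size, _ = mod[0], mod[1]
            if len(mod) > 2:
                offset = mod[2]
            else:
                offset = cursor
                cursor += size
            members.append(genes[offset : offset + size])
        return members

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class PlantedTruth:
    """Ground truth labels of a simulated scenario."""

    genes: list[str]
    modules: list[list[str]]
    planted_genes: set[str]
    core_genes: set[str]  # members of the densest planted module
    de_genes: set[str] = field(default_factory=set)
    gwas_genes: dict[str, set[str]] = field(default_factory=dict)
    snp_enriched_genes: set[str] = field(default_factory=set)


def simulate_ppi_network(
    scn: SyntheticScenario,
) -> tuple[PPINetwork, PlantedTruth]:
    """Erdős–Rényi background with planted dense modules.

    Background pairs appear with probability ``edge_prob``; a pair
    internal to one or more planted modules appears with the maximum of
    the covering densities.  All confidences are 1.0.  Isolated genes
    are not part of the returned network (consistent with the loader's
    universe convention) but remain in the truth labels.
    """
    genes = scn.gene_ids()
    members = scn.module_members()
    for mod, mem in zip(scn.planted_modules, members):
        if mod[1] < scn.edge_prob:
            import warnings

            warnings.warn(
                "planted module density below background edge_prob: "
                "module will not stand out",
                stacklevel=2,
            )
    idx = {g: i for i, g in enumerate(genes)}
    n = scn.n_genes
    prob = np.full((n, n), scn.edge_prob)
    for mod, mem in zip(scn.planted_modules, members):
        ids = [idx[g] for g in mem]
        sub = np.ix_(ids, ids)
        prob[sub] = np.maximum(prob[sub], mod[1])
    rng = scn._rng(0)
    draw = rng.random((n, n))
    iu = np.triu_indices(n, k=1)
    hit = draw[iu] < prob[iu]
    g = nx.Graph()
    for i, j in zip(iu[0][hit], iu[1][hit]):
        g.add_edge(genes[i], genes[j], confidence=1.0)
    net = PPINetwork(graph=g, min_confidence=0.0, source="simulated")
    densest = max(
        range(len(members)),
        key=lambda i: scn.planted_modules[i][1],
        default=None,
    ) if members else None
    truth = PlantedTruth(
        genes=genes,
        modules=members,
        planted_genes=set().union(*members) if members else set(),
        core_genes=set(members[densest]) if densest is not None else set(),
    )
    return net, truth


def simulate_expression(
    truth: PlantedTruth, scn: SyntheticScenario
) -> ExpressionMatrix:
    """Gaussian expression with mean-shifted DE genes.

    Every gene is iid normal(0, noise_sd); genes selected as truly DE
    (planted-module genes with probability ``frac_de_in_planted``,
    others with ``frac_de_background``) get ``de_effect`` added in the
    case samples.  The chosen DE genes are recorded in
    ``truth.de_genes``.
    """
    if scn.n_case < 2 or scn.n_control < 2:
        raise ValueError("need >= 2 samples per group")
    rng = scn._rng(1)
    genes = truth.genes
    planted = truth.planted_genes
    p_de = np.array(
        [scn.frac_de_in_planted if g in planted else scn.frac_de_background
         for g in genes]
    )
    is_de = rng.random(len(genes)) < p_de
    n_samples = scn.n_case + scn.n_control
    values = rng.normal(0.0, scn.noise_sd, size=(len(genes), n_samples))
    values[is_de, : scn.n_case] += scn.de_effect
    case_ids = [f"case{i + 1:02d}" for i in range(scn.n_case)]
    ctrl_ids = [f"ctrl{i + 1:02d}" for i in range(scn.n_control)]
    samples = case_ids + ctrl_ids
    df = pd.DataFrame(values, index=genes, columns=samples)
    df.index.name = "gene"
    groups = pd.Series(
        [CASE] * scn.n_case + [CONTROL] * scn.n_control, index=samples
    )
    truth.de_genes = {g for g, d in zip(genes, is_de) if d}
    return ExpressionMatrix(values=df, groups=groups)


def simulate_gwas_and_snps(
    truth: PlantedTruth, scn: SyntheticScenario
) -> tuple[GWASCatalog, pd.DataFrame, pd.DataFrame]:
    """GWAS catalog, SNP association table and gene intervals.

    Genes tile a toy genome end-to-end on one chromosome (fixed length,
    fixed gap), so interval assignment is exhaustively verifiable.  Each
    gene carries ``n_snps_per_gene`` evenly spaced intragenic SNPs.  SNP
    p-values are uniform(0,1) except inside the planted core genes,
    where P(p < snp_alpha) is multiplied by ``snp_sig_enrichment`` (a
    two-component uniform mixture, so the enrichment factor is exact).
    The primary disease's GWAS genes are drawn with
    ``gwas_overlap_frac`` from planted-module genes; additional catalog
    diseases (``n_diseases > 1``) get uniform random gene sets.
    """
    rng = scn._rng(2)
    genes = truth.genes
    intervals = []
    pos = 1
    for g in genes:
        intervals.append((g, "chr1", pos, pos + GENE_LENGTH - 1))
        pos += GENE_LENGTH + GENE_GAP
    intervals_df = pd.DataFrame(intervals, columns=INTERVAL_COLUMNS)

    enriched_genes = set(truth.core_genes)
    truth.snp_enriched_genes = enriched_genes
    rows = []
    a = scn.snp_alpha
    e = scn.snp_sig_enrichment
    for g, _, start, end in intervals:
        if scn.n_snps_per_gene == 0:
            continue
        offsets = np.linspace(0, GENE_LENGTH - 1, scn.n_snps_per_gene)
        positions = (start + np.round(offsets)).astype(int)
        u = rng.random(scn.n_snps_per_gene)
        if g in enriched_genes and e > 1.0:
            # mixture: with prob e*a the p-value is uniform below alpha
            sig = u < e * a
            p = np.where(
                sig,
                rng.random(scn.n_snps_per_gene) * a,
                a + rng.random(scn.n_snps_per_gene) * (1 - a),
            )
        else:
            p = u
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        for j, (posn, pv) in enumerate(zip(positions, p)):
            rows.append((f"snp_{g}_{j + 1}", "chr1", int(posn), float(pv)))
    snps_df = pd.DataFrame(rows, columns=SNP_COLUMNS)

    # GWAS genes overlap the planted core (densest module) when one
    # exists, falling back to the planted union
    planted = sorted(truth.core_genes or truth.planted_genes)
    background = sorted(set(genes) - set(planted))
    n_from_planted = min(
        int(round(scn.gwas_overlap_frac * scn.n_gwas_genes)), len(planted)
    )
    n_from_bg = scn.n_gwas_genes - n_from_planted
    chosen = list(
        rng.choice(planted, size=n_from_planted, replace=False)
    ) + list(rng.choice(background, size=n_from_bg, replace=False))
    diseases = {"disease_1": frozenset(chosen)}
    for d in range(2, scn.n_diseases + 1):
        extra = rng.choice(genes, size=scn.n_gwas_genes, replace=False)
        diseases[f"disease_{d}"] = frozenset(extra)
    catalog = GWASCatalog(diseases)
    truth.gwas_genes = {d: set(s) for d, s in diseases.items()}
    return catalog, snps_df, intervals_df


@dataclass
class SyntheticDataset:
    """Complete simulated study: all inputs plus ground truth."""

    scenario: SyntheticScenario
    network: PPINetwork
    truth: PlantedTruth
    expression: ExpressionMatrix
    catalog: GWASCatalog
    snps: pd.DataFrame
    intervals: pd.DataFrame


def simulate_scenario(scn: SyntheticScenario) -> SyntheticDataset:
    """Run all three generators for one scenario."""
    network, truth = simulate_ppi_network(scn)
    expr = simulate_expression(truth, scn)
    catalog, snps, intervals = simulate_gwas_and_snps(truth, scn)
    return SyntheticDataset(
        scenario=scn,
        network=network,
        truth=truth,
        expression=expr,
        catalog=catalog,
        snps=snps,
        intervals=intervals,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Materialise a dataset in the input formats the pipeline reads.

    Returns a mapping of logical name -> file path.  Interaction scores
    are written on the STRING-style 0-1000 integer scale.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "catalog": outdir / "gwas_catalog.tsv",
        "snps": outdir / "snps.tsv",
        "intervals": outdir / "gene_intervals.tsv",
        "truth": outdir / "planted_truth.tsv",
    }
    with open(paths["network"], "w") as fh:
        for u, v, c in sorted(ds.network.edges()):
            fh.write(f"{u}\t{v}\t{int(round(c * 1000))}\n")
    ds.expression.values.to_csv(paths["expression"], sep="\t")
    ds.expression.groups.to_csv(paths["samples"], sep="\t", header=False)
    ds.catalog.to_tsv(paths["catalog"])
    ds.snps.to_csv(paths["snps"], sep="\t", header=False, index=False)
    ds.intervals.to_csv(paths["intervals"], sep="\t", header=False, index=False)
    with open(paths["truth"], "w") as fh:
        for g in ds.truth.genes:
            labels = []
            if g in ds.truth.planted_genes:
                labels.append("planted")
            if g in ds.truth.core_genes:
                labels.append("core")
            if g in ds.truth.de_genes:
                labels.append("de")
            fh.write(f"{g}\t{','.join(labels) if labels else '-'}\n")
    return {k: str(v) for k, v in paths.items()}
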