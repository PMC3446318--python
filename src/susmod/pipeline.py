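"""End-to-end orchestration: load inputs, discover the susceptibility
module and its core, and validate them against GWAS genes and SNP
association p-values.

All thresholds live in :class:`RunConfig` with the method's defaults:
interaction confidence >= 0.7, DE and clique-enrichment p < 0.05, core
fraction 0.10, SNP significance alpha 1e-3, 100,000 permutations.
Every run writes a manifest recording the seed, thresholds and universe
sizes, and outputs are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from .expression import de_gene_set, read_expression, test_differential_expression
from .gwas import GWASCatalog, permutation_set_enrichment
from .modules import (
    EmptyModuleError,
    build_susceptibility_module,
    compute_average_shortest_path_lengths,
    enrich_cliques,
    extract_core_module,
    module_summary,
    write_edge_list,
    write_gene_list,
)
from .network import enumerate_maximal_cliques, load_ppi_network, write_cliques
from .snps import (
    alpha_sensitivity_sweep,
    assign_snps_to_genes,
    read_gene_intervals,
    read_snp_table,
    snp_set_enrichment,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    network_path: str = ""
    expression_path: str = ""
    samples_path: str = ""
    catalog_path: str = ""
    snps_path: str = ""
    intervals_path: str = ""
    disease: str = "disease_1"
    output_dir: str = "susmod_out"

    min_confidence: float = 0.7
    de_alpha: float = 0.05
    use_adjusted: bool = False
    detection_cutoff: float | None = None
    clique_alpha: float = 0.05
    core_fraction: float = 0.10
    snp_alpha: float = 1e-3
    n_perm: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("min_confidence", 0.0, 1.0),
            ("de_alpha", 0.0, 1.0),
            ("clique_alpha", 0.0, 1.0),
            ("snp_alpha", 0.0, 1.0),
            ("core_fraction", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} out of range ({lo}, {hi}]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Key-value config file; explicit keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full discovery + validation pipeline.

    Stages: network load -> maximal cliques -> differential expression
    -> per-clique Fisher enrichment -> module assembly -> per-gene ASPL
    -> core extraction -> permutation GWAS enrichment (module, core) ->
    SNP enrichment of the core (when SNP inputs are configured).
    Returns the report dictionary that is also written to
    ``report.json``; with no enriched clique the run short-circuits with
    a structured "no module" report (and :class:`EmptyModuleError` is
    raised after writing it).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage network: loading %s", config.network_path)
    net = load_ppi_network(config.network_path, config.min_confidence)
    cliques = enumerate_maximal_cliques(net, min_size=2)
    write_cliques(cliques, outdir / "cliques.tsv")

    logger.info("stage de: testing expression %s", config.expression_path)
    expr = read_expression(config.expression_path, config.samples_path)
    de = test_differential_expression(
        expr,
        threshold=config.de_alpha,
        use_adjusted=config.use_adjusted,
        detection_cutoff=config.detection_cutoff,
    )
    de.to_csv(outdir / "de_results.tsv", sep="\t")

    # universe: genes both in the filtered network and measured on the array
    universe = net.nodes & set(expr.genes)
    de_genes = de_gene_set(de) & universe
    universe_cliques = [c for c in cliques if set(c) <= universe]

    logger.info(
        "stage enrichment: %d cliques in a %d-gene universe, %d DE",
        len(universe_cliques), len(universe), len(de_genes),
    )
    records = enrich_cliques(
        universe_cliques, de_genes, universe, config.clique_alpha
    )
    module = build_susceptibility_module(records, net, config.disease)

    report: dict = {
        "disease": config.disease,
        "config": asdict(config),
        "universe_size": len(universe),
        "n_cliques": len(universe_cliques),
        "n_de_genes": len(de_genes),
        "versions": {
            "susmod": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
    }

    if module.empty:
        report["status"] = "no_module"
        _write_json(report, outdir / "report.json")
        raise EmptyModuleError(
            f"no clique enriched at p < {config.clique_alpha}: empty module"
        )

    aspl = compute_average_shortest_path_lengths(module)
    core = extract_core_module(module, aspl, config.core_fraction)
    write_gene_list(module.genes, outdir / "sum_genes.txt")
    write_gene_list(core.genes, outdir / "core_genes.txt")
    write_edge_list(module.edges, outdir / "sum_edges.tsv")

    report["status"] = "ok"
    report["summary"] = module_summary(module, core)
    report["module_genes"] = sorted(module.genes)
    report["core_genes"] = sorted(core.genes)

    if config.catalog_path:
        catalog = GWASCatalog.from_tsv(config.catalog_path)
        gwas = catalog.diseases.get(config.disease)
        if gwas is None:
            raise ValueError(
                f"disease {config.disease!r} not in catalog "
                f"({sorted(catalog.diseases)[:5]} ...)"
            )
        enr = {}
        for label, target in (("sum", module.genes), ("core", core.genes)):
            res = permutation_set_enrichment(
                target, gwas, universe,
                n_perm=config.n_perm, seed=config.seed,
            )
            enr[label] = res.as_dict()
        report["gwas_enrichment"] = enr
        report["summary"]["gwas_in_network"] = len(set(gwas) & universe)

    if config.snps_path and config.intervals_path:
        snps = read_snp_table(config.snps_path)
        intervals = read_gene_intervals(config.intervals_path)
        assignment = assign_snps_to_genes(snps, intervals)
        res = snp_set_enrichment(
            snps, assignment, core.genes, alpha=config.snp_alpha
        )
        report["snp_enrichment"] = res.as_dict()
        sweep = alpha_sensitivity_sweep(
            snps, assignment, core.genes,
            alphas=[1e-2, 5e-3, 1e-3, 5e-4, 1e-4],
        )
        sweep.to_csv(outdir / "snp_alpha_sweep.tsv", sep="\t", index=False)

    _write_json(report, outdir / "report.json")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report


def multi_disease_report(
    modules: dict[str, frozenset[str]],
    cores: dict[str, frozenset[str]],
) -> dict:
    """Cross-disease overlap summary: pairwise Jaccard matrices and the
    union of the core modules."""
    from .gwas import jaccard_matrix, union_of_sets

    return {
        "jaccard_sum": jaccard_matrix(modules).to_dict(),
        "jaccard_core": jaccard_matrix(cores).to_dict(),
        "union_of_cores": sorted(union_of_sets(cores.values())),
    }
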