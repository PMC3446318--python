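"""Config-driven end-to-end run on a materialised synthetic data set.

Writes all inputs to disk in their native TSV formats, then executes
the whole chain (network -> cliques -> DE -> enrichment -> module ->
core -> GWAS permutation -> SNP enrichment) through RunConfig.
Equivalent shell usage: `susmod simulate` followed by `susmod run-all`.
"""

import json
import tempfile
from pathlib import Path

from susmod import (
    RunConfig,
    SyntheticScenario,
    run_full_pipeline,
    simulate_scenario,
    write_dataset,
)

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_scenario(SyntheticScenario(n_snps_per_gene=100, seed=5))
    paths = write_dataset(ds, Path(tmp) / "data")
    config = RunConfig(
        network_path=paths["network"],
        expression_path=paths["expression"],
        samples_path=paths["samples"],
        catalog_path=paths["catalog"],
        snps_path=paths["snps"],
        intervals_path=paths["intervals"],
        disease="disease_1",
        output_dir=str(Path(tmp) / "out"),
        use_adjusted=True,
        core_fraction=0.2,
        n_perm=20_000,
        seed=5,
    )
    report = run_full_pipeline(config)

print("summary row:", json.dumps(report["summary"], indent=2))
gwas = report["gwas_enrichment"]
print(f"core GWAS enrichment: fold {gwas['core']['fold']:.1f}, "
      f"p = {gwas['core']['p_empirical']:.1e}")
snp = report["snp_enrichment"]
print(f"core SNP enrichment: fold {snp['fold']:.2f}, FDR {snp['FDR']:.3f}")
print("-> the discovered core is validated by both independent "
      "genetic signals, mirroring the intended use of the method.")
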