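# susmod

Discovery and genetic validation of **disease susceptibility modules**
from case/control gene expression and a protein–protein interaction
(PPI) network.

Complex diseases perturb groups of interacting genes rather than single
genes. `susmod` implements a network-medicine workflow for finding
those groups and asking whether they carry independent genetic disease
signal. It is aimed at computational biologists who have (1) a
confidence-scored PPI edge list (STRING-style), (2) a case/control
expression matrix, and optionally (3) GWAS gene lists and/or a
genome-wide SNP association table.

## Method

1. **Network filtering.** Interactions with combined confidence ≥ 0.7
   (STRING 0–1000 or 0–1 scales auto-detected) form the gene universe.
2. **Maximal cliques.** All maximal cliques down to size 2 are
   enumerated (Bron–Kerbosch with pivoting).
3. **Differential expression.** Per-gene two-sided pooled-variance
   Student's *t*-test, *P* < 0.05, with optional Benjamini–Hochberg
   correction and a bead-array detection-score filter.
4. **Clique enrichment.** Each clique of size *s* with *a* DE members
   is tested one-sided against Hypergeometric(*N*, *K*, *s*) where *K*
   is the number of DE genes in the *N*-gene universe (Fisher's exact
   test, enrichment direction); cliques with *P* < 0.05 are kept.
5. **Susceptibility module (SuM).** The union of enriched cliques is
   mapped back onto the network, each gene once, keeping all induced
   edges; the SuM contains both DE genes and their clique neighbours.
6. **Core module.** Genes are ranked by average shortest path length
   (ASPL) inside the SuM — the mean unweighted distance to all
   reachable module genes — and the lowest decile (default
   `core_fraction = 0.10`) forms the core: the most interconnected
   genes.
7. **GWAS validation.** The overlap of a GWAS gene set with the SuM or
   core is compared with 100,000 permutations in which the whole set is
   redrawn uniformly from the universe: fold = observed/expected,
   empirical *P* = (r+1)/(n+1).
8. **SNP validation.** With per-SNP association *p*-values and gene
   intervals (1-based inclusive), significant SNPs (*p* < α = 10⁻³) are
   tested for concentration inside the module genes:
   *P* = P(X ≥ x), X ~ Hypergeom(n, m, k), with estimators
   FP = k·m/n, TP = x − FP, FDR = FP/x and the odds ratio of a
   significant SNP inside vs outside the subset, plus an α-sensitivity
   sweep.

Cross-disease utilities cover pairwise Jaccard similarity of modules,
the union of cores, pleiotropy-stratified gene sets and a replication
χ²-test on the 2×2 membership table.

## Worked example

Everything is runnable without external data through the synthetic
generator, which plants a dense 10-gene core inside a 40-gene module on
a 500-gene background network and concentrates the DE and genetic
signal there (see `docs/methods.md`):

```bash
python examples/01_discover_module.py
```

```
universe: 497 genes, 1280 maximal cliques
DE genes (BH < 0.05): 27
enriched cliques: 54
susceptibility module: 41 genes (27 DE + clique neighbours)
core module (20% lowest ASPL): ['G001', 'G003', 'G004', 'G005', 'G006', 'G008', 'G010', 'G016', 'G023']
-> 7/9 core genes belong to the planted dense module: the ASPL ranking concentrates on the planted structure.
```

The module (41 genes) gathers the differential signal plus its clique
neighbourhood; ranking by ASPL then isolates the planted
highly-interconnected genes. Validation of such a core against GWAS
genes and SNPs (`examples/04_full_pipeline.py`) prints:

```
core GWAS enrichment: fold 25.4, p = 5.0e-05
core SNP enrichment: fold 7.48, FDR 0.134
```

i.e. the core contains ~25× more GWAS genes than matched random sets,
and significant SNPs are concentrated in its genes.

The same pipeline is available from the shell:

```bash
susmod simulate --seed 42 --outdir demo/
susmod run-all run.yaml        # YAML mirror of RunConfig
susmod enrich-snp demo/snps.tsv demo/gene_intervals.tsv core_genes.txt
```

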