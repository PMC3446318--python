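# Methods

## Model and assumptions

`susmod` operationalises a simple network-medicine premise: in a
complex disease, differentially expressed (DE) genes are not scattered
randomly over the protein–protein interaction (PPI) network but
concentrate in densely wired neighbourhoods, and the most
interconnected genes of those neighbourhoods are the ones most likely
to carry germline disease variants. The workflow therefore has two
halves — *discovery* (expression + network → module → core) and
*validation* (module vs GWAS genes, core vs SNP associations) — that
use disjoint data, so the validation is not circular.

The discovery half assumes:

* interactions above the confidence threshold are equally trustworthy
  (edge weights are used only for filtering, never for path lengths);
* expression intensities are approximately normal within groups with
  comparable variances (pooled-variance Student's *t*; a Welch variant
  is available behind a flag for heteroscedastic data);
* a clique — a fully connected gene set — is the unit of local
  wiring: DE enrichment is judged clique by clique, one-sided, against
  the hypergeometric law on the universe of genes that are both in the
  filtered network and measured on the array. Genes can only be
  observed in a module if both memberships hold, which is why that
  intersection is the universe for every downstream statistic.

## Statistics

**Clique enrichment.** For a clique of size *s* with *a* DE members,
*P* = P(X ≥ a), X ~ Hypergeom(N, K, s) — the one-sided Fisher exact
test in the enrichment direction. Cliques are judged at raw *P* < 0.05
by default; the method's selection step is intentionally liberal and
the correction burden is carried by the downstream validation. An
across-clique Benjamini–Hochberg option exists but is off by default.

**ASPL and the core.** For module gene *g*, ASPL(*g*) is the mean
unweighted shortest-path distance to every *reachable* other module
gene within the module's induced subgraph (averaging over reachable
nodes is the Cytoscape NetworkAnalyzer convention; genes with no
reachable partner are ineligible for the core). The core is the
`ceil(fraction × module size)` genes with the smallest ASPL, ties
broken lexicographically for determinism. A flag computes ASPL on the
whole network instead of the module, for sensitivity analysis. Note a
structural property of the reachable-only convention: a gene in a tiny
disconnected component can have ASPL 1.0, the attainable minimum, so
fragmentary modules pull such genes into the core ahead of the hub
genes of the main component. This is faithful to the convention; it is
the main reason the recovery scenario (below) uses the FDR-corrected
DE workflow, which keeps spurious two-gene components rare.

**Permutation GWAS enrichment.** Each permutation redraws the whole
query set uniformly without replacement from the universe — jointly
redrawing the set is distributionally identical to replacing every
gene with a random one, and makes the null exactly hypergeometric, so
the expected overlap q·t/N is analytically checkable. Internally the
q-subset is taken as the q smallest of N iid uniform keys
(vectorised argpartition), which is an exact uniform subset sampler.
The empirical *p* uses the add-one estimator (r+1)/(n_perm+1), so it
is never zero; a result with no exceedance reads "< 1/n_perm". A
pooled variant sums observed and permuted overlaps across diseases for
totals-row analyses.

**SNP enrichment.** With *n* total SNPs, *m* inside the gene subset,
*k* significant (*p* < α, strict) and *x* significant inside,
*P* = P(X ≥ x), X ~ Hypergeom(n, m, k). The companion estimators are
FP = k·m/n (the hypergeometric null mean, equal to Σ x·pmf(x) to
machine precision — the identity is asserted in the tests),
TP = x − FP, FDR = FP/x, the odds ratio
(x/(m−x)) / ((k−x)/((n−m)−(k−x))), and the fold x/FP. SNPs assigned to
several subset genes count once: all four symbols are SNP counts.
Linkage disequilibrium is assumed comparable inside and outside the
subset, so no LD pruning is performed. Undefined ratios (x = 0, zero
denominators) are reported as NaN/None rather than raised.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `min_confidence` | 0.7 | interaction confidence filter (0–1; 700 on the 0–1000 scale) |
| `de_alpha` | 0.05 | DE call threshold on raw (or BH-adjusted) *p* |
| `clique_alpha` | 0.05 | per-clique Fisher threshold |
| `core_fraction` | 0.10 | fraction of module genes kept as core |
| `n_perm` | 100000 | permutations for the GWAS null |
| `snp_alpha` | 1e-3 | SNP significance cutoff (chosen by α-sensitivity sweep) |
| `detection_cutoff` | none | drop genes with detection score below this in *every* sample |

Gene identifiers are opaque strings; no identifier mapping is done and
callers must harmonise IDs across the network, expression, catalog and
interval inputs. Genomic coordinates are 1-based with inclusive ends;
a converter from 0-based half-open BED is provided.

## Synthetic data: what it emulates and what it does not

The generator produces a complete study: an Erdős–Rényi background
network G(n, p) with planted dense modules (a pair covered by several
modules gets the maximum density), Gaussian case/control expression
with a mean shift δ added to cases for true-DE genes, a GWAS catalog
whose primary gene list overlaps the planted core, and a toy genome
(1 kb genes, 100 bp gaps, single chromosome) whose SNP *p*-values are
uniform except inside the planted core genes, where P(p < α) is
multiplied by an exact mixture factor *e*.

Canonical scenario (the package default, used by the recovery test and
the acceptance script): 500 genes, background edge probability 0.01
(mean degree ≈ 5, desk-scale stand-in for a sparse confidence-filtered
interactome), a 40-gene planted module wired at density 0.15
containing a nested 10-gene clique (density 1.0) as the planted core,
δ = 2σ with 10+10 samples (per-gene power ≈ 0.95 before correction),
DE probability 0.8 inside the planted module and 0 outside (background
false positives then come only from the *t*-test itself), 15 GWAS
genes of which 60% are drawn from the planted core, and SNP
significance enrichment ×5 at α = 10⁻³. The recovery run uses the
BH-adjusted DE workflow and `core_fraction = 0.2`, chosen so that the
expected core size (ceil(0.2 × ~45) ≈ 9–10) matches the 10-gene
planted core — with a deliberately mismatched size the Jaccard index
to the truth would be bounded well below 1 by arithmetic alone.

What passing on this generator shows: the statistical machinery is
correctly wired end to end — DE power where planted, clique enrichment
finds dense DE neighbourhoods, ASPL ranking isolates the densest
substructure, and the two validation nulls are calibrated. What it
does not show: behaviour under scale-free degree distributions, probe
noise and normalisation artifacts, correlated expression, LD between
SNPs, or identifier mismatch — all absent from the generator by
design. Real interactomes are three orders of magnitude larger; all
algorithms are polynomial except clique enumeration, whose output size
is the practical bound on dense networks.

The SNP fold x/FP estimates the planted factor *e* only in the limit
m ≪ n: because FP uses the overall significance rate, the estimand is
e/(1 + (e−1)·m/n) (≈ 4.63 for e = 5 at m/n = 0.02). The recovery test
compares against this design value with a Monte-Carlo tolerance.

## Numerical and design choices

* Score-scale auto-detection: any score > 1 implies the 0–1000 STRING
  dialect; the threshold comparison is inclusive (≥).
* Duplicate edges (including reversed order) keep the maximum score;
  self-loops are dropped; genes without a retained edge are not part
  of the universe.
* Clique enumeration relies on Bron–Kerbosch with pivoting; output is
  canonicalised (sorted members, lexicographic order) so runs are
  reproducible; correctness is defined against an exhaustive-subset
  oracle in the tests, not against a particular algorithm.
* Genes with zero variance in both groups get t = 0, p = 1 and a flag
  instead of an error (constant probes are common after quantisation).
* Missing expression values are rejected: microarray matrices are
  complete, and silent imputation would change the statistics.
* Module edges are the full induced subgraph, not only within-clique
  edges: the induced edges are required for ASPL and contain the
  within-clique edges as a subset.
* `ceil` rounding for the core size and lexicographic tie-breaks keep
  the core deterministic.
* All random draws flow through `numpy.random.default_rng` seeded from
  the scenario/config seed (generator sub-streams are spawned per
  component), so identical seeds give byte-identical outputs.
* Empty modules (no enriched clique) short-circuit with a structured
  "no module" report and a dedicated CLI exit code (3) rather than an
  unstructured failure.

## Known limitations

* No probe-to-gene summarisation, normalisation or empirical-Bayes
  moderation: the expression input is assumed preprocessed.
* No identifier mapping across input files.
* Per-clique testing without multiplicity correction (by default)
  follows the method's design; the module list is therefore liberal
  and meaningful only together with the validation stage.
* The reachable-only ASPL convention favours small disconnected
  components (see above); inspect component structure when a module is
  fragmented.
* Permutation and SNP nulls ignore gene length, degree and LD biases;
  enrichment against these structured nulls is outside scope.
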