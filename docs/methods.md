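# Methods

## Scope and data model

`cohealth` analyzes a *collection* of expression experiments from several
species. Each experiment is a genes × samples matrix (microarray
log-intensities or RNA-seq counts) plus a per-sample metadata table of
experimental factors. Experiments are analyzed completely independently of
each other — removing one experiment never changes another experiment's
network, modules or exported interactions — and only their final ranked
gene lists meet in the cross-species consensus stage. Experiments with six
or fewer samples are excluded up front, as are experiments for which no
soft-threshold power yields a scale-free network ("no modules found");
both produce machine-readable exclusion records rather than errors.

## Health phenotype scorecards

Sample health is encoded by a per-experiment scorecard applied to the
metadata: a base score per age category (young untreated wildtype 1, old
0), plus a signed increment per treatment rule, ±0.2 by default and
adjustable per rule when effect sizes warrant it. Genetic perturbations
(knock-downs, knock-outs, transgenes, natural variants) are treated as
treatments. A free-form arithmetic formula over factor columns is available
as an escape hatch for experiments whose design does not decompose into
base + increments; when present it replaces the rule sum. Scores are
dimensionless and comparable only within one experiment; the pipeline never
relates scores across experiments. A constant score vector is flagged at
scoring time and turns into an exclusion at module selection, where the
eigengene correlation would be undefined.

## Network construction

1. **Preprocessing.** Counts are converted to transcripts per million
   (TPM_g = 10⁶·(c_g/l_g)/Σ_h(c_h/l_h)) and low-expression genes removed
   (default: TPM ≥ 1 in ≥ 50% of samples). Matrices are log2(x+1)
   transformed unless they already look log-scaled; the heuristic treats a
   matrix maximum ≤ 50 as already logged, since log2 expression values sit
   well below that while linear intensities and TPMs exceed it. Optional
   quantile normalization (ties receive the mean of the spanned reference
   values) or per-gene Z-scoring are provided; Z-scoring provably leaves
   all Pearson-based downstream results unchanged and exists for parity
   checks. Sample outliers can be removed by average-linkage clustering on
   Euclidean distance with a configurable cut height, retaining the largest
   cluster; this automates a per-experiment manual step, trading judgment
   for reproducibility.
2. **Soft threshold.** Unsigned adjacency a_ij = |cor_ij|^β. β is the
   smallest integer in 1–20 whose connectivity distribution fits
   p(k) ∝ k^(−γ): soft connectivities are split into 10 equal-count bins,
   the per-bin degree *density* (count/(n·width)) is regressed on the mean
   connectivity in log10–log10 space, and the fit must reach R² ≥ 0.80 with
   a negative slope. Equal-count bins require the density normalization —
   per-bin frequencies would be constant by construction; an equal-width
   binning mode using plain frequencies is available as an option. A
   degenerate degree distribution (all k equal) sets a not-scale-free flag
   instead of crashing.
3. **Topological overlap.** TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
   (min(k_i,k_j) + 1 − a_ij) with the diagonal excluded from k and the TOM
   diagonal set to 1; computed vectorized and verified against a
   triple-loop oracle to 1e-10.
4. **Module detection.** Average-linkage hierarchical clustering on
   1 − TOM (scipy). Tree cutting is a deterministic two-stage procedure
   written for this package: a static cut at 99% of the dendrogram height
   yields base clusters, then up to two levels of recursive splitting
   divide a base cluster when the top merge of its sub-dendrogram is
   separated from the next merge by at least 5% of the branch height and
   both halves meet the minimum module size (30 by default). Clusters
   below the minimum size become label 0 (unassigned); there is no
   reassignment stage, so borderline genes stay unassigned rather than
   being attributed to the nearest module. Labels are ordered by
   decreasing module size.
5. **Eigengene.** First right singular vector of the row-standardized
   module submatrix, unit L2 norm across samples, oriented to correlate
   positively with the module's mean standardized profile (fallback for
   perfectly balanced ± modules: positive loading on the lexicographically
   first gene). Variance explained is the top-eigenvalue ratio.

## Module selection and gene lists

Module–trait association is the Pearson correlation between eigengene and
health score, with a two-sided p from the Student t transform (df = n − 2).
The retention rule is a raw p < 0.05 per experiment — no multiple-testing
correction across modules, matching the filter the analysis is built
around; a Benjamini–Hochberg switch exists but is off by default. From
each retained module two lists of at most 30 genes are cut: by soft
connectivity (hubs) and by |kME| (module membership). Ties are broken
lexicographically by gene ID and logged. Each gene's direction versus
health is sign(kME)·sign(r): membership in a negatively health-correlated
module inverts the gene's apparent direction.

## Consensus, interactions, graphs

Ortholog mapping is table-driven (species, native ID, human symbol);
many-to-one mappings collapse to one evidence line per experiment, and
one-to-many mappings contribute each symbol once. A symbol present in
lists from ≥ 2 distinct species enters the consensus report with its
species, experiment count and direction aggregation (unanimous or
"mixed"). Per experiment, the interaction threshold is the
linear-interpolation 95% quantile of all off-diagonal adjacency values
(configurable to module-restricted values); hub-pair edges strictly above
it are exported, dropping pairs that collapse to the same human symbol.
"Above" is taken literally: an edge exactly at the threshold is excluded.
The consensus graph keeps hub–hub edges and non-hub *connectors* adjacent
to ≥ 2 distinct hubs in the merged cross-experiment graph; parallel edges
keep the maximum adjacency with the provenance union. Two-hop
neighborhoods are breadth-first expansions with all induced edges; the
spanning-tree simplification is the maximum-weight spanning forest
(Kruskal on decreasing adjacency, ties broken by edge names), which keeps
the stronger of two alternative paths while preserving connectivity. The
separate minimum interaction score (default 0.2) filters the per-experiment
edge-list export; it is applied to the TOM-based interaction score by
default with a switch for raw adjacency, since either reading of "the
interaction score" is defensible.

## Permutation tests

*Consensus-count null*: each of 10,000 permutations replaces every
experiment's retained-module lists with equally sized uniform draws
(without replacement within a module; modules of one experiment draw
independently by default, with a pooled option) from that species' full
measured gene universe, reruns the consensus and records the count. The
empirical p is the plain fraction of permutations with count ≥ observed
(upper tail); an optional (b+1)/(n+1) correction is provided but off by
default. The report includes the standard 14-entry quantile row (0–100%).
*Degree rank-sum test*: genes ranked ascending by interaction degree
(average ranks for ties); the p is the fraction of equally sized random
selections with a strictly higher rank sum. Small instances can be
enumerated exhaustively instead of sampled.

## Synthetic data

The generator plants a one-factor model per module,
x_gs = λ_g f_ms + noise_scale·√(1−λ_g²) ε_gs, so that the eigengene is an
estimate of f_m, hub genes (largest |λ|) provably lead the soft-connectivity
and |kME| rankings, and recovery checks are analytic rather than asymptotic.
Metadata (balanced young/old, random treatments) is scored by the default
scorecard to give the latent health score. For a health-associated module
the factor is built by Gram–Schmidt so its *realized in-sample* correlation
with the standardized score equals the configured target exactly; this
makes the power of the p < 0.05 filter at a planted correlation of 0.8 and
n = 12 essentially 1, while *unplanted* modules (factor drawn independently
of the score) calibrate the null flag rate at the nominal 5%. Defaults —
two species × two experiments, 12 samples, one health module of 30 genes
(5 conserved hubs, loading 0.95; member loadings ≈ √0.55 with jitter), 60
independent noise genes, log-intensity scale 8 + 2x — reflect the small
public healthspan experiments the pipeline targets: barely more than the
six-sample inclusion floor, modules at the minimum detectable size, and a
majority of unstructured genes. The counts platform draws per-gene
log-normal base means (median 100) and Poisson counts around
base·exp(0.7x), with uniform 500–5000 bp gene lengths, to exercise the TPM
and low-count paths. Conserved hubs share human symbols across species in
the generated ortholog table; other module genes map to species-unique
symbols and noise genes have no ortholog entry.

What the generator does *not* emulate: probe-level microarray artifacts,
batch effects, read-level RNA-seq, correlated noise between modules, or
realistic gene-universe sizes (thousands). Passing tests therefore
demonstrate correctness of the machinery and its statistical calibration
under the factor model, not performance on repository-scale data.

## Numerical choices and limitations

- Problem sizes in tests and the acceptance script (90–170 genes,
  12–200 samples, 100–200 replicate seeds, 10,000 permutations) are chosen
  so the full study re-runs in well under a half hour on one core while
  keeping Monte-Carlo error far below the asserted tolerances.
- Quantiles everywhere use linear interpolation between order statistics.
- Constant genes are dropped (with a log entry) before correlation;
  constant phenotypes and empty filters are hard errors.
- Per-experiment seeds derive from the study seed by SHA-256 of the
  experiment ID, keeping runs reproducible and experiments independent.
- The scale-free criterion (R² ≥ 0.80, smallest qualifying power) is a
  reproducible surrogate for per-experiment manual power choice; on very
  small gene universes the degree distribution is unstable and the
  criterion may reject otherwise usable experiments.
- Module detection without a reassignment stage under-assigns borderline
  genes; detected health modules may also absorb a few correlated noise
  genes at 12 samples, which the top-30 connectivity cut tolerates.
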