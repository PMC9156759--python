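# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic generator does
and does not emulate, and the known limitations.

## Data model and normalization

Counts are kept as a sparse genes × cells matrix of non-negative integers
with per-cell metadata (sample, lineage genotype, condition, optional
cluster) and per-gene flags (mitochondrial prefix `mt-`, case-sensitive;
immune/erythroid exclusion genes *Ptprc*, *Hba-a1*, *Hba-a2*, *Hbb-bs*;
reporter symbol, default `tdTomato`). Gene symbol lookups are exact and
case-sensitive. Log-normalization is the standard per-cell transform
`x' = ln(1 + s·x / colsum)` with scale factor `s = 1e4` (the common
library default; the transform is column-local, so permuting cells
permutes columns and nothing else). Normalization refuses cells with zero
total counts: QC must run first.

Variable-gene selection follows the variance-stabilizing recipe: a
lowess trend of log10 variance on log10 mean of the raw counts (span
0.3 — the exact bandwidth is this package's choice), per-gene
standardization against the trend, clipping at √N, and ranking by the
variance of the clipped values. Ties break lexicographically so the
selection is deterministic and invariant to gene order.

## QC and lineage-purity filtering

QC applies three criteria jointly on the raw counts of the unfiltered
input (not sequentially): detected-feature count within an inclusive
window `[min_features, max_features]` (default 500–5000; the lower cutoff
is per-sample configurable because it is tuned per library in practice),
mitochondrial read fraction strictly greater than 0.06, and any nonzero
count in an exclusion gene. Per-criterion removal counts are reported and
may overlap.

The purity filter implements the reporter statistic
`condGeneProb(cluster, sample)` = fraction of that group's cells with
reporter count > 0. Detection is binarized at count > 0 on raw counts;
the upstream tool the statistic originates from may binarize with a
data-driven threshold, so this is a documented convention, not a claim of
equivalence. Two rules apply in a fixed order: (1) every (cluster,
sample) group with `condGeneProb < 0.8` is removed entirely; (2) from the
remainder, every cell with zero reporter reads is removed. Running (2)
first could rescue groups that rule (1) is meant to remove, which is why
the order is fixed and tested. After filtering, every surviving cell has
at least one reporter read — asserted exhaustively in the tests.

## Binned-control module scoring

For a gene set, all genes are ranked by dataset-average log-normalized
expression and cut into `n_bins = 24` equal-frequency bins (ties to the
lower bin). Each target gene draws `n_ctrl = 100` control genes without
replacement from its own bin; a bin smaller than `n_ctrl` falls back to
sampling with replacement with a warning (this only matters for small
gene universes). The score is the per-cell mean over target genes minus
the mean over the pooled control multiset. Consequences that the tests
assert: the score is exactly zero (to float summation order) when every
gene has the same expression vector; adding a constant to all of one
cell's values leaves that cell's score unchanged; amplifying the targets
in a subset of cells raises their scores relative to the rest. Scores
are deterministic given the seed. Cell-cycle phase is `G1` when both the
S and G2M scores are ≤ 0, otherwise the larger score wins.

The aggregate ECM score pools the union of the collagen, glycoprotein
and proteoglycan sets (the core matrisome). Whether published analyses
used exactly this union or a combined published list is not always
recoverable; the union is this package's documented reading.

## Composition testing

Normalized cluster proportions are compared between two conditions via
`log2FD = log2(p̂_B + 0.5/n_B) − log2(p̂_A + 0.5/n_A)`. The
pseudo-proportion `0.5/n` keeps the statistic finite when a cluster is
absent from one condition and is always added, so the statistic is a
difference of logs and negates bit-exactly under condition swap (this
matters for tie handling in the permutation null). The null permutes
condition labels across cells (`n_permutations = 1000` by default;
stratified permutation by e.g. sample is available), and
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_permutations)` — the add-one
estimator, so `p ≥ 1/(1+n)`. BH-FDR is applied across clusters within
the comparison. The decision rule is `FDR < 0.05` and `|log2FD| > 0.58`
(≈1.5-fold), both strict. The permutation replaces the bootstrap
internals of the tool the rule originates from; it feeds the same
decision inputs (log2FD, FDR) and its type-I error is verified by
simulation to sit near the nominal 5%.

## Meta-cells and correlation

Meta-cells are built by PCA (20 components on the scaled variable genes,
values clipped at ±10) → shared-nearest-neighbor graph (k = 20, Jaccard
edge weights) → Louvain multilevel modularity at resolution 10. The high
resolution deliberately over-fragments the data into small homogeneous
groups; groups below `min_size = 5` cells are dropped together with their
cells. Averaging expression and scores within meta-cells suppresses
per-cell count noise before Pearson correlation — the tests verify that
driver-gene correlations are strictly stronger on meta-cells than per
cell. Constant vectors get `r = 0` by convention rather than NaN.
Score–gene correlation excludes the score's own gene set (it would
trivially top the ranking) and returns the top 100 by `r`, ties broken by
symbol; score–TF correlation returns the top 10.

TF activity is a signed, weighted mean of z-scored target profiles:
`activity(m, tf) = Σ_t w_t · mode_t · z_t(m) / Σ_t w_t` with genes
z-scored across meta-cells. This is a transparent stand-in with the same
interface as enrichment-based activity inference; regulons with no
present targets are excluded with a warning. Whether meta-cells should be
built on batch-corrected coordinates is an open question in general; here
they are built on plain PCA, which is adequate for the batch-homogeneous
synthetic data and documented as the convention.

## Ligand–receptor crosstalk

The consensus database keeps ordered (ligand, receptor) pairs supported
by at least `min_sources = 2` of the supplied source tables, with full
source provenance retained; the retained set is monotone decreasing in
`min_sources`. Ortholog translation accepts a many-to-one table and drops
pairs with unmapped members (one-to-many rows are an error — ambiguous
orthology must be resolved upstream). Complexes (multi-subunit receptors)
are out of scope; pairs are gene-to-gene.

For each ordered cluster pair, an interaction is testable when the ligand
is detected in ≥ `min_fraction = 0.1` of sender cells and the receptor in
≥ that fraction of receiver cells. The score is
`MeanLR = (mean lognorm ligand in sender + mean lognorm receptor in
receiver)/2`, tested one-sided (specifically high means) against a null
that reassigns cells to clusters preserving cluster sizes, with the
add-one p estimator. On data where all clusters share one distribution
the p-values are approximately uniform (KS-checked in the tests).
Differential networks subtract condition A from condition B per directed
cluster pair over significant interactions, substituting 0 for an
interaction absent or non-significant in a condition (a documented
choice), and emit ligand/receptor up/down gene sets with symbols
appearing on both sides of one role removed from both.

## Markers and differential expression

Candidate genes must pass two pre-test gates: `min.pct` (fraction of
expressing cells ≥ threshold in either group; 0.3 for one-vs-rest
markers, 0.25 for condition DEG) and an absolute log fold change
(`ln(mean(expm1(x̃_in)) + 1) − ln(mean(expm1(x̃_out)) + 1)`, the
convention of recent toolchain versions; 0.25 / 0.3 respectively). Gated
genes are tested by Wilcoxon rank-sum on log-normalized values: full
enumeration of the permutation distribution with midranks when the
pooled group has ≤ 16 cells (exact even under ties), the tie-corrected
normal approximation otherwise. The rank-sum is a stand-in for a hurdle
regression model; the gates and BH multiplicity handling, not the test
statistic, are the procedure's substantive content, and this deviation
is deliberate and documented. Condition DEG tables are filtered to
adjusted p < 0.01 (strict).

Cluster similarity merges datasets on their shared gene universe,
averages log-normalized expression per cluster, selects the 500 most
variable genes of the merged data (or the full intersection if smaller,
with a warning) and reports the Pearson matrix (symmetric, unit
diagonal).

## Synthetic data generator

Counts follow `count(g, i) ~ NegBin(mean = lib_i · p_{t(i),g} · m_{g,i},
size = θ)`: each cell type has a normalized rate profile over the gene
universe; `m` multiplies the ECM program targets and the planted driver
and TF-target genes by `(1 + β·a_i)` with per-cell activity
`a ~ Beta(1,5)` in sham and `Beta(5,2)` after injury for the fibroblast
analog (`Beta(1,20)` elsewhere), and multiplies planted ligand/receptor
genes by their fold boost in sender/receiver types. Reporter counts are
Poisson: `λ_pos = 3` for labelled lineage cells (labelling efficiency
0.95), an ambient channel (probability 0.01 of `Poisson(0.5)`) otherwise;
contaminant types only see the ambient channel. Mitochondrial genes
receive a per-type fraction (2%) of each cell's rate mass, with a
configurable "damaged" subpopulation at 15% for exercising QC.

Chosen study conditions: library sizes are log-normal with median ≈5000
counts; dispersion `θ = 10`, i.e. mild overdispersion typical of UMI
data; the baseline rate profile is log-normal (σ = 1.2) with the planted
program genes on elevated baselines (collagens and other matrisome genes
are among the more highly expressed genes in matrix-producing cells).
The baseline profile is drawn from a separate `universe_seed` so
independent sampling runs share their gene universe — this is what makes
cross-dataset cluster-similarity comparisons meaningful. Per-stage
presets fix the scenario sizes: `purity` (5,000 cells, one
reporter-negative contaminant cluster), `ecm` (2,000 cells), `drivers`
(3,000 cells, 1,000 genes, 20 drivers), `composition` (2,000 cells per
condition, one cluster tripling its share), `crosstalk` /
`null_crosstalk`, `markers` (30 genes doubled in one cluster after
injury), and the fast `smoke` preset for end-to-end runs.

What the generator does **not** emulate: batch effects requiring
integration, gene–gene co-expression beyond the planted programs,
zero-inflation beyond what the negative binomial produces, spliced /
unspliced layers, and realistic cluster geometry (types are separated by
planted marker boosts). Passing tests therefore demonstrate that each
procedure recovers the effects it targets under a faithful statistical
null, not that it is robust to every artifact of real tissue data.

## Numerical conventions and determinism

All randomness flows through explicit seeds: the pipeline config seed
fans out to stages as `stage_seed = (seed·100 + stage_index) mod 2³¹`, so
any stage can be re-run independently. Louvain uses Python's `random`
module (seeded and restored around the call); numpy's `default_rng`
drives everything else. Stage outputs are TSV with floats at six
significant digits, and re-running a config reproduces every output
byte-identically (hash-verified in the manifest and asserted in tests).
Degenerate inputs have fixed conventions: constant vectors correlate at
0, empty expression bins fall back to replacement sampling with a
warning, clusters with < 3 cells are skipped in marker detection, and
QC / purity errors carry per-criterion breakdowns.

## Limitations

- The rank-sum DEG test and the z-mean TF activity are stand-ins with the
  same interfaces as the heavier model-based methods they replace;
  effect rankings agree on strong planted signals but p-value magnitudes
  are not comparable to hurdle-model output.
- Purity filtering assumes clusters computed on pooled data and applies
  the group rule per sample; it does not model ambient-RNA contamination
  or doublets explicitly.
- The composition test permutes cells globally by default; replicate-
  aware (per-sample) inference is out of scope, and the stratified option
  only conditions on the stratum sizes.
- Meta-cell construction is resolution-driven; meta-cell counts scale
  with data size and the resolution parameter rather than being fixed.
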