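# Methods

This note records the models and procedures rhodonet implements, the
defaults it ships, and the numerical and design choices a maintainer
should know about.

## Preprocessing

Transcriptome route: probe-level matrices are collapsed to gene level
(probes hitting more than one gene are discarded; several probes on one
gene are averaged per sample), log2-transformed, averaged across replicate
chips per condition, and standardized per gene to robust z-scores
`(x − median) / MAD`.  The MAD is deliberately unscaled (no 1.4826
normal-consistency factor): the score is defined as the number of median
absolute deviations from the median, and every downstream statistic is
correlation-based, hence invariant to the row scale anyway.

Proteomics route: column-median (central tendency) normalization of the
log-scale abundances, removal of proteins with more than two missing
values, then per-protein z-scores over observed entries (sample sd,
divisor n−1).  Filtering runs before the z-score so the z-score's
requirement of at least three observed values per row is automatically
met; the CLI exposes a flag to filter before normalization instead.
Missing values are never imputed — correlations use pairwise-complete
observations — except inside the eigengene SVD, where row means fill the
gaps for that decomposition only.

Rows with MAD = 0 (or sd = 0) are set to all-zero and reported rather than
dropped, so the gene universe stays aligned across datasets; the
correlation code treats them with a Pearson-style fallback (below).

## Network construction

Biweight midcorrelation: each row is median-centred and weighted with
Tukey biweights computed from `u = (x − med) / (9 MAD)`; bicor is the
inner product of the weighted vectors normalized by their norms.  Rows
with MAD = 0 have no robust scale and fall back to plain mean-centring,
which makes their pairs Pearson-like; the fallback gene list is attached
to the result.  With missing data, the per-row transform is computed on
each row's observed entries and pairs are renormalized over their common
positions.  The strict per-pair variant (recomputing medians on each
pairwise-complete subset) would cost O(n² m log m) for no practical
difference at desk scale, so it is not implemented.  Pairs supported by
fewer than 4 common observations raise an error; the preservation module
accepts a lower bound (`min_obs=2`) because a six-condition proteomics
layer with up to two missing values per row cannot guarantee four shared
observations, and its statistics are null-calibrated anyway.

Signed adjacency `((1 + r)/2)^β` with β = 18 — fixed, not tuned by
scale-free fit; the analysis this package implements treats β as part of
the protocol.  Topological overlap uses the standard formula
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with unit
diagonal.  Whether clustering runs on 1 − TOM (default) or 1 − adjacency
is a flag (`use_tom`), since the underlying protocol leaves this at the
default of its module-detection ecosystem.

## Module detection

Average-linkage clustering of the dissimilarity is cut by a span-relative
static branch cut: co-expression dendrograms at this scale show genuine
modules completing low in the tree while unconnected background genes
chain together in a dense band just below the maximum merge height, so the
cut is placed at `h_min + (0.92 + 0.02·deep_split) · span`.  Candidate
branches below the minimum module size (default 15) are dropped.  Each
surviving branch must beat a random-matrix check: its eigengene variance
share must exceed 1.3× the Marchenko–Pastur edge `(1 + √(s/c))²/s` for a
same-shaped noise block — this is what keeps pure-noise inputs almost
entirely unassigned.  A PAM-like stage then assigns stragglers to the
module of highest kME when that kME reaches the module's own membership
range (10th percentile of member kME); modules whose eigengenes correlate
above `1 − merge_cut_height` (default 0.15) are merged iteratively; a
final kME pass moves a gene only when its membership elsewhere strictly
exceeds that in its own module (the zero reassignment threshold); labels
are then reassigned by decreasing size, with the conventional size-ordered
colour aliases for readability only.

This cut is an approximation of the Dynamic Hybrid heuristics, not a
re-implementation; correctness is judged by planted-structure recovery
(adjusted Rand index ≥ 0.9 on the reference scenario), not label-for-label
agreement with any other tool.  Determinism: genes are sorted
lexicographically before clustering, so the partition is invariant to row
order up to label names; randomness enters only through seeded resampling.

Eigengenes are unit-norm first right-singular vectors of the
row-standardized module submatrix, sign-oriented so their correlation with
the module's mean profile is non-negative.  kME is bicor between each
gene and each eigengene (Pearson available).

Module stability resamples conditions with replacement, reruns detection,
and reports per reference module the median and IQR of the best-match
overlap.  Condition clustering uses 1 − Pearson between condition
profiles with plain bootstrap (BP) support — the fraction of
gene-bootstrap replicates in which the exact leaf set reappears.  BP is a
deliberate simplification of multiscale-bootstrap AU values: ordinary BP
is conservative but has the same interpretation and no extra machinery.

## Module preservation

Observed statistics per module, computed on the datasets restricted to
the shared (ortholog-mapped, reference-relabelled) genes:

* density, in the test data: meanCor (mean off-diagonal bicor), meanAdj,
  propVarExplained (test eigengene variance share), meanKME;
* connectivity, reference vs test: cor.kIM (correlation of intramodular
  connectivities), cor.kME (correlation of member kMEs), cor.cor
  (correlation of the vectorized within-module correlation matrices);
* cor.kMEall: correlation over all common genes of kME to the module's
  eigengene, reference vs test (bicor by default, Pearson by flag).

The null permutes module membership among the common genes — sizes
preserved, expression untouched, so marginal distributions are intact.
`Z = (obs − null mean)/null sd`; Zdensity and Zconnectivity are medians
within their class, Zsummary their mean.  medianRank is permutation-free:
modules are ranked per observed statistic (rank 1 = most preserved,
descending values) and the per-module median rank reported; undefined
statistics (modules under 3 genes, zero-variance nulls) are excluded from
ranks rather than imputed.

Quality statistics run the same machinery with test := reference.  In
that self-comparison the three connectivity components are identically 1
for the observed module and for every permuted gene set, so their null sd
is 0 and their Z scores are undefined by construction; Zsummary.qual then
falls back to Zdensity.qual.  This is a property of the self-comparison
design, not a failure mode: quality is a statement about density.

Interpretation thresholds follow the established convention: Zsummary > 2
weak-to-moderate, > 10 strong evidence; lower medianRank = better
preserved.  A held-out-conditions variant (`reproducibility_in_subset`)
reports which modules clear the 2/5/10 thresholds when given conditions
are excluded.

## Local Network Similarity

Correlations among the n ortholog genes are clipped to |r| ≤ 1 − 1e-12
and atanh-transformed (the clip keeps the unit diagonal finite without
materially changing any off-diagonal value).  For pair k, LNS is the
Pearson correlation of rows k of the two pair-aligned matrices after
deleting the pair's own self-entry; Pearson because Fisher-transformed
correlations are what the transform is designed to make
correlation-friendly.  The null shuffles the ortholog mapping table (full
permutations, fixed points allowed) and re-applies the shuffled table
end-to-end, i.e. the test matrix is reindexed on both axes so pairs sit
on the diagonal again; network topology is untouched.  The alternative
null that permutes node labels on the lookup axis only — breaking the
component alignment, a genuinely different distribution — is available
behind `shuffle_nodes`.  Empirical p-values are computed against the
pooled null by default (`per_pair` switches to each pair's own null
column); the pooled reading matches how the null is summarized (mean,
range, "fraction of pairs above every null value").

Within-species LNS splits the conditions into two disjoint halves
(⌊C/2⌋ / ⌈C/2⌉), computes a bicor matrix per half, scores every gene with
the identity mapping, and averages over repeats (default 100).

The per-module median of LNS (median-LNS) is compared with cor.kMEall by
Pearson correlation across modules; both are connectivity-style measures
of preservation and track each other on planted data (r ≈ 0.7–0.9 on the
default scenario).

## Gene-set statistics

Hypergeometric upper tail P(X ≥ k), summed in log space via logsumexp of
log-pmf terms.  BH-FDR (statsmodels) across all module × set tests
jointly — the conservative pooling; per-category pooling can be had by
calling `ora` per category.  Sets are intersected with the universe and
dropped below 3 genes.

Packaging test: genes ranked ascending by the robust z of their signal;
for each module, 1000 random same-sized gene sets are drawn from the full
scored universe (module genes not excluded — sets are "randomly selected
sets of genes"), and one-sided rank-sum tests (normal approximation of
the Mann–Whitney U, ties from overlapping draws counted half) are run in
both directions at α = 0.01.  Verdict "packaged": the module is
significantly greater than ≥ 85% of random sets and no random set is
significantly greater than it; "excluded" is the mirror image; otherwise
neutral.  The criterion mixes a fraction threshold with a zero-opposite
condition; this reading is recorded in the report header so alternative
readings can be diffed.  Being rank-based, verdicts are invariant under
any strictly monotone transform of the scores.

## Synthetic data generator

The generator emulates the data regime the package targets, with full
ground truth:

* Species A: `n_genes_A` genes (default 1500) over `n_conditions_A`
  conditions (default 30).  Each planted module m has a latent
  standard-normal profile e_m over conditions; member genes are
  `ρ·e_m + √(1−ρ²)·noise` (default ρ = 0.8; module sizes default
  300…15, spanning the size range such studies report).  Background genes
  are i.i.d. noise; `background_fraction` is the minimum unplanted
  fraction (1.0 = no modules at all).  Conditions are exchangeable —
  every downstream statistic uses only correlation structure, so no
  condition ordering or block design is simulated.
* Species B: one ortholog per sampled A gene (`ortholog_fraction`,
  default 0.6, matching the roughly-60% one-to-one ortholog coverage of
  the motivating comparison) over its own `n_conditions_B` (default 40).
  Preserved modules keep their membership with a freshly drawn latent
  profile — preservation is about correlation structure, not matched
  conditions.  Non-preserved modules are destroyed by re-partition: fresh
  groups of the original sizes are drawn from the pool of
  non-preserved-module plus background genes, and the rest of the pool
  becomes background.  This keeps B's module-size spectrum identical
  between the preserved and non-preserved cases (so preservation
  statistics respond to structure, not size) while making the original
  membership look random in B.
* Proteomics layer: a random gene subset (default 1000) and condition
  subset (default 6) of species A with Gaussian noise (sd 0.5) and
  missing-at-random entries (rate 0.1) — mimicking a small label-free
  relative-quantification dataset.  It does not model MS intensity
  distributions, censoring-type missingness, or shared-peptide effects.
* Packaging signal: standard-normal per gene, with one module (default
  module 1) shifted by `packaging_shift` MAD units (default +3).

All layers are deterministic functions of `(spec, seed)` through fixed
per-layer substreams, so any layer can be regenerated independently.

What passing tests on this generator does and does not show: recovery and
discrimination results demonstrate that the statistics respond correctly
to planted correlation structure of realistic size and strength; they do
not certify behaviour under batch effects, probe-level artifacts,
non-Gaussian expression, condition-correlated missingness, or modules
with heterogeneous within-module correlation — none of which the
generator emulates.

## Problem sizes and runtimes

The test suite and the acceptance script run at desk scale by choice: the
reference recovery scenario uses 5 × 40-gene modules with 200 background
genes; preservation checks use 200 membership permutations (the
protocol's full setting is 1000; Z scores stabilize well before that, and
`n_perm` is a parameter everywhere); LNS nulls use 100 map permutations;
the packaging test uses its full 1000 random sets.  The default pipeline
scenario (1500 genes) completes in under a minute on one CPU.

## Known limitations

* The tree cut is a behavioural approximation of Dynamic Hybrid; on data
  with strongly nested or size-heterogeneous module structure the two can
  split branches differently (the eigengene merge stage recovers most
  over-splitting).
* Quality-pass connectivity statistics are degenerate by design (above).
* Pairwise-complete bicor uses per-row (not per-pair) medians under
  missingness.
* `blockwise` scaling devices are intentionally absent; the full n × n
  matrices are held in memory, which is fine up to a few thousand genes.
* The packaging test's normal approximation of the rank-sum statistic is
  inaccurate for modules under ~10 genes; the minimum module size (15)
  keeps it in its valid range.
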