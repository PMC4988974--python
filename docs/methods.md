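# Methods

## Scope and model

`conetdiff` compares the co-expression architecture of two related
transcriptomes over a shared ortholog space. The underlying model is the
standard weighted co-expression one: genes in a module track a common
latent per-tissue expression profile (the eigengene) through gene-specific
loadings, and cross-species differences appear either as loss of module
structure (non-preservation) or as changed connectivity of individual
genes within an otherwise matched module (hub divergence). All statistics
operate on log-transformed FPKM-like values; no count-level modeling is
attempted.

## Pre-processing

Transcripts are mapped to orthologs by best BLASTX-style hits (one best
hit per transcript, e-value <= 1e-5; the mapping is consumed precomputed,
never recomputed). When several transcripts share an ortholog, the one
with maximal sample SD is kept (the most informative signal); ties break
lexicographically so the collapse is deterministic. Only orthologs
expressed in both species survive, sorted so both matrices share one gene
index. "Excessive missing values" is quantified as > 50% missing per gene
(no published figure exists; the threshold is exposed). Sample outliers
are flagged — not removed — when their standardized mean inter-sample
correlation falls below −2.5. Dataset comparability is summarized as the
Pearson correlation of ranked per-gene mean expression (equivalently
Spearman's rho of the mean profiles), which is scale-free across
platforms.

## Differential expression

The screen is the classical equal-variance two-sample t-test with the
pooled variance `s_p^2 = (SD_1^2(n_1−1) + SD_2^2(n_2−1))/(n_1+n_2−2)` and
`df = n_1+n_2−2`; Welch's correction is deliberately not used because the
pooled formula and df define the procedure being reproduced. The
low-variance pre-filter removes exactly `floor(m * p/100)` genes with the
smallest pooled variance (default p = 30, read as a percentile of the
pooled-variance distribution — an absolute variance cutoff would be
data-scale dependent). BH is applied after filtering, so the multiplicity
is the filtered gene count. The test is two-sided by default (flag
exposed). Degenerate genes follow explicit conventions: zero pooled
variance with equal means gives p = 1, with unequal means p = 0 plus a
warning.

Calibration is measured with the pre-filter disabled: a between-species
mean shift does not raise within-species pooled variance, so the filter is
orthogonal to the signal and would remove planted genes at random —
measuring the filter, not the test. The filter's own contract (exact
removal count) is tested separately.

## Networks

Signed adjacency `a_ij = ((1+cor_ij)/2)^beta` maps correlation −1 to 0 and
+1 to 1, preserving sign information that an unsigned network would
discard. Correlations are computed across each species' own samples (8 and
6 by default) with pairwise-complete observations. The soft threshold is
chosen as the smallest candidate power whose binned log–log connectivity
fit reaches R² = 0.8 (10 bins, log10 frequency on log10 mean bin
connectivity), falling back with a warning to the best-fitting candidate;
one beta (default 14) is shared between the two species so connectivity
scales are comparable, overridable per species. TOM is computed by one
matrix product — with a zero diagonal the shared-neighbor sum
`l_ij = (A²)_ij` automatically excludes `u ∈ {i, j}`, resolving the
ambiguity in the summation index; the matrix path is verified against a
naive triple loop to 1e-10.

## Module detection

Average-linkage hierarchical clustering runs on DisTOM (scipy's
implementation; genes sorted first so input order is irrelevant). The cut
is a hybrid rule driven by one `deepsplit` level in 0–4:

1. **Static cut.** Merge heights in these dendrograms are bimodal —
   co-expressed genes merge low, noise merges and noise attachments high.
   The static cut is placed at the Otsu threshold (minimum within-class
   variance split) of the merge-height distribution, scaled by
   `1 − 0.1·deepsplit`. A quantile-of-heights rule was evaluated first and
   rejected: background genes chain onto module branches at heights just
   below any high quantile, so a cut there absorbs large numbers of noise
   genes into every module (planted-structure recovery dropped to
   ARI ≈ 0.3 versus ≈ 0.9 for the bimodal rule).
2. **Gap split.** Each branch is recursively split at the middle of its
   largest internal merge-height gap while that gap exceeds
   `0.25 − 0.05·deepsplit`.
3. Branches smaller than `min_module_size` (default 20) become "grey"
   (unassigned). Modules take the conventional color palette in decreasing
   size order, ties broken by the smallest member gene ID, so the largest
   module is always "turquoise".

Degenerate input with all pairwise distances equal cuts below every merge,
leaving all genes grey — documented rather than special-cased.

Module eigengenes are the first right singular vectors of the
gene-standardized member expression (no column centering, so a module of
identical genes yields their common profile), oriented so the correlation
with the module's mean standardized profile is non-negative. kME is every
gene's correlation with each eigengene. Enrichment is a one-sided
hypergeometric upper tail against a user-supplied background with
Bonferroni correction over the number of tested sets; no ontology DAG
logic is included.

## Preservation

Reference-module definitions are imposed on the test dataset (mapped, not
re-detected). Four statistics per gene set: density = {mean intramodule
correlation in test, mean intramodule signed adjacency in test};
connectivity = {correlation of intramodular connectivities ref vs test,
correlation of in-module kME ref vs test}. The permutation null draws
same-size gene sets without replacement from the shared universe (seeded);
`Z = (obs − null mean)/null SD` per statistic, `z_density` and
`z_connectivity` are medians of their pairs, and `Z_summary` is their
mean. This is a reduced, fully specified analogue of the published
composite (which aggregates many more statistics the same way:
medians within groups, then the mean); the standard thresholds (< 2 /
2–10 / > 10) are kept. One caveat observed on synthetic data: when the
universe mixes module and background genes, random sets inherit a
module/background connectivity contrast that is itself cross-species
reproducible, so connectivity Z scores can sit below zero even for
preserved modules; the density statistics dominate, and `Z_summary`
discriminates cleanly (preserved ≫ 2, noise < 2, gold control near 0). A
"gold" random module of configurable size is always evaluated identically
as a negative control. Fisher tests in the module cross-tabulation are
two-sided.

## Robustness

Networks are binarized before attack; since no published conversion rule
exists, the default keeps the top 5% of off-diagonal weights (percentile
rule, so densities are comparable across networks of different size — a
prerequisite for comparing `V_max` between species), with an absolute
threshold available. Attacks remove nodes one at a time in decreasing
initial centrality (static ranking; recalculated ranking behind a flag),
ties by node ID; `sigma(i/N)` is the largest-component fraction of the
*original* N after each removal, so the trajectory ends at exactly 0 and
`R = (1/N)Σσ ≤ (N−1)/(2N)`. The random control averages 25 seeded
orderings. Closeness on disconnected graphs follows the within-component
convention; eigenvector centrality is the principal eigenvector of the
largest component (equal values on a two-node component), zero elsewhere.

## Divergent hubs

`K_i = k_i/k_max` uses adjacency row sums restricted to the module (the
published value's exact basis — TOM, adjacency, or degree — is unstated;
adjacency row sums are the most direct reading of "connectivity").
Matched module pairs come from the most Fisher-significant overlap
partner. The hub threshold is strict `K_i > 0.6`; divergence is
`|ΔK_i| ≥ 0.2`, a default chosen because it isolates exactly the three
highlighted genes in the bundled 17-row reference table; both are
parameters. No significance test is attached to ΔK_i — none exists to
reproduce.

## Synthetic data

The generator emulates the study conditions: two species with 8 and 6
tissue samples, log-scale expression with gene intercepts ~ N(5, 1),
planted modules whose eigengene is a per-tissue mean-shift pattern plus a
standard-normal latent, loadings uniform on [0.5, 1], and Gaussian noise
(default SD 0.1). Non-preserved modules are generated as independent noise
in species B. Divergent hubs keep their loading but observe a blend of the
module eigengene with a private latent factor (mixing weight
`1 − hub_delta/3`) in the attenuated species — attenuating the loading
alone cannot realize a connectivity gap, because at beta = 14 the
adjacency saturates near the top of the correlation range. The noise
default of 0.1 reflects the estimator's limits at study-scale sample
sizes: with 8/6 samples, correlation sampling error propagates through the
14th power into background |ΔK_i| fluctuations of ±0.4 at SD 0.2, which
would swamp any plantable hub gap; at SD 0.1 background fluctuation stays
below ±0.2 while planted hubs realize |ΔK_i| ≈ 0.45. Duplicate transcripts
share the ortholog's latent signal with doubled noise SD, so the max-SD
collapse rule has a deterministic right answer. Metabolite profiles are
constructed by exact orthogonal mixing, so realized gene–metabolite
correlations equal their targets.

What passing tests on this generator do *not* show: real RNA-seq carries
count noise, library-size and length biases, correlated batch structure,
and ortholog-mapping errors, none of which are modeled. Recovery rates
here are upper bounds for real data.

## Problem sizes and runtime choices

The test suite and acceptance script run at desk scale: ~480–530 genes
(4 planted modules of 60/50/40/30 plus 300 background), 100 permutations
for Z-summary, 10–20 seeded replicates for rate estimates, and 200 random
matrices (n ≤ 50) for the TOM oracle. These sizes give stable rates while
keeping the full suite around a minute; all scale linearly upward through
the same APIs.

## Known limitations

- The tree cut is a simplified hybrid, not the full published dynamic
  tree-cut algorithm; module boundaries on real data will differ in
  detail, though the deepsplit knob behaves analogously.
- Z-summary uses 4 statistics rather than the published catalogue;
  absolute Z values are not comparable to published tables, only the
  categories are.
- The pipeline builds networks on significant DEGs (falling back to all
  tested genes when fewer than `min_network_genes` pass), so module
  content depends on the DEG screen upstream.
- `V_max` depends strongly on the binarization rule; published values are
  reproducible only approximately even with the original data, since the
  conversion rule was never printed.
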