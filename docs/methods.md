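# Methods

This note documents the models, conventions and numerical choices behind
`immunopanel`, including the places where the underlying procedures are
under-specified in common practice and a concrete convention had to be
fixed.

## Data model

Counts are probes × samples with a `stage` tag (`raw` →
`background_subtracted` → `normalized`); stage preconditions are enforced
so, e.g., differential expression cannot accidentally run on raw counts.
Gene identity is the gene symbol, matched case-sensitively: panel symbols
are controlled vocabulary and silent case-folding would hide annotation
errors. RCC lane files use the sectioned-CSV dialect
(`<Header>`, `<Lane_Attributes>`, `<Code_Summary>` with
CodeClass,Name,Accession,Count), one file per lane; positive-control
names carry the spike-in concentration (`POS_A(128)`) so the annotation
round-trips losslessly. Edge lists whose maximum score exceeds 1 are
interpreted as the 0–1000 database dialect and divided by 1000 — the one
deliberate silent coercion, and it is logged.

## Background model and exclusion

The background is estimated from the negative-control probes pooled
across all lanes of an analysis unit: mean *m*, sample standard deviation
*s* (n − 1 denominator), exclusion threshold *m* + 2*s*. Background
subtraction removes *m* from endogenous and housekeeping counts, floored
at zero; control probes are untouched. A gene is excluded when its mean
raw count across the unit's samples is strictly below the threshold.
Pooling across lanes (rather than per-lane background) and the per-unit
exclusion scope (tissue × experiment, so the gene universe is constant
within every contrast) are package conventions; both are recorded in the
QC report.

## Normalization

Per-lane factors are `grand / lane`, where `lane` is the lane's geometric
mean of the relevant control probes and `grand` is the arithmetic mean of
the lane values (so lane geometric means {100, 200} give factors
{1.5, 0.75}). Order: background subtraction → positive-control factor →
housekeeping factor, the housekeeping geometric means being computed on
the positive-normalized counts. After normalization the per-lane
geometric means of the selected housekeeping genes are equal to within
1e-9 relative.

One consequence worth stating precisely: multiplying all counts of one
lane by *c* > 0 (controls included) is compensated *within* that lane
exactly, but the grand reference — an average over lanes — shifts, so the
normalized matrix changes by a single global constant. No data-derived
reference can avoid this. Every downstream statistic (log-ratios, *t*,
Z-scores, Spearman ρ) is invariant to a global scale, and the tests
assert exactly that form of invariance (entry-wise ratios constant to
1e-9).

### geNorm reference selection

Candidate housekeeping gene stability is
`M_j = mean_{k≠j} SD_samples( log2 x_j − log2 x_k )`; the gene with the
highest M is removed iteratively (ties broken lexicographically by
symbol, for determinism) until two remain; the final two are mutually
indistinguishable by M and are ordered lexicographically. The pairwise
variation `V_{k,k+1}` is the SD across samples of the difference between
log₂ normalization factors built from the top *k* and top *k + 1* genes;
the selected set is the smallest *k* ≥ 3 with V < 0.15 (the conventional
cutoff), falling back to the *k* minimizing V. The simulator plants 2
unstable housekeeping genes (extra log-normal noise, σ = 1 log₂ unit);
these are removed first in ≥ 95% of seeds.

## Pseudocount

`log2(x)` is taken as `log2(0.5)` when `x = 0` (equivalently, only zero
counts receive the +0.5 pseudocount). This keeps positive counts exact
while avoiding −∞; at panel count scales the induced bias is negligible.
The same rule feeds geometric means of background-subtracted counts.

## Differential expression

The default per-gene model is ordinary least squares of log₂ normalized
counts on a case indicator; the coefficient is the log₂ group difference
and its Wald *t* equals the pooled-variance two-sample *t* with n − 2
degrees of freedom (computed in closed form, vectorized across genes).
Zero residual variance with a non-zero difference is flagged degenerate
(p = 0). The optional simplified negative-binomial model fits a GLM with
log link on raw counts, a log normalization-factor offset, and a
method-of-moments dispersion (floored at 1e-8); non-convergent genes fall
back to the log-linear model and the per-gene `model_used` records it.
Model choice is explicit and global per run rather than per-gene — a
per-gene selection heuristic would be an unreproducible black box.
A mixture model for responder heterogeneity is deliberately not fitted;
the strong/low responder structure lives in the simulator, where it is
observable ground truth.

The reported log₂ ratio is `log2(mean_case / mean_ref)` of normalized
counts (not the model coefficient), matching the ratio-of-averages
convention used for heatmap exports. BH adjustment (via statsmodels) is
applied within each contrast separately; a gene is significant iff
*q* < 0.05 and |log₂ ratio| > 1, both strict. Sequential within-treatment
contrasts (W5 vs W1, …) reuse the same machinery with case = later time.

## Gene-set and pathway scores

Global and directed significance are defined in the README; the directed
form (signed mean of signed squares, square-rooted with sign restored)
was chosen because it reduces to ±global under unanimous direction and to
0 under perfect cancellation, and satisfies |directed| ≤ global exactly.
Pathway scores: per-gene Z-scale across samples, PC1 via SVD, sample
scores re-Z-scaled (ddof = 1), sign oriented so the mean gene loading is
positive (higher score = higher average pathway expression; also
stabilizes regression tests). Zero-variance genes are dropped with a log
entry; a set with no varying genes yields no score. Genes in multiple
sets are scored independently in each.

## Cell profiling

Cell-type score = mean log₂ normalized expression of the type's marker
genes, per sample. Scores are comparable within a cell type across
groups, never across cell types (the output layout is one comparison
table per cell type for this reason). The packaged marker map has 13
immune cell types (leukocytes through NK cells) of mouse gene symbols.
For multi-marker types a confidence p-value tests whether markers
co-vary: the statistic is the mean pairwise Pearson correlation across
samples and the null distribution comes from independently permuting each
marker's sample order (seeded; p = (1 + hits) / (n_perm + 1), one-sided).
This permutation form is a package convention — the idea being tested is
"do these markers track a common abundance signal" — and calibrates
uniformly under independence. All cell types are reported regardless of
confidence. Group comparisons use the two-sided Wilcoxon rank-sum test,
exact (no ties, total n ≤ 20) or normal-approximated with continuity
correction; all-tied data returns p = 1.

## Association

Spearman ρ with average-rank ties and the two-sided *t* approximation;
a pathway × endpoint cell is significant iff |ρ| > 0.5 and *p* < 0.05,
and non-significant cells are masked in the export. Constant endpoints
give an undefined, masked ρ. Hierarchical clustering is UPGMA on
Euclidean distances via scipy; scipy's tie handling is deterministic
(cluster-index order), which the package accepts in lieu of a
lexicographic tie-break. PCA centers (and by default unit-scales)
columns, orients components by positive mean loading, and reports
per-group 95% ellipses from the bivariate-normal quantile of the group's
coordinate covariance. Venn overlaps enumerate all region cardinalities
exactly for 2–5 sets.

## Network clustering

Edges with combined score ≥ 0.7 (inclusive) between genes of interest are
kept. MCL: self-loops weighted by each node's maximum incident edge
weight, column-stochastic normalization, then alternating expansion
(matrix squaring) and inflation (entry-wise power 1.5, column
renormalization) with per-column pruning below 1e-8, until the maximum
entry change falls below 1e-6 (cap 200 iterations; non-convergence
returns the current clustering with a warning). Clusters are the
connected components of the limit matrix's support; they always refine
the input graph's components, are invariant to node relabeling and to
uniform edge-weight scaling.

A caution from our own measurements: at inflation 1.5, MCL does **not**
split modules that remain bridged by several above-threshold edges — for
two 6-node modules at within-score ~0.9 joined by 3–4 edges at ~0.75,
recovery is below 50% for every standard self-loop convention, reaching
~100% only at inflation ≥ 1.8. A *single* just-above-threshold bridge is
split reliably at 1.5 (tested). The simulator therefore plants
between-module edges below the 0.7 confidence cutoff, so module recovery
is exercised through the filter-then-cluster path the pipeline actually
uses.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study geometry (two acute arms, a chronic
four-tissue-week time course, n = 8 per group, vehicle matching), and the
count structure the analysis assumes: NB counts
(`var = μ + αμ²`) with baseline means log₂-normal(7, 2) and dispersion
Gamma(shape 4, scale 0.025) (mean 0.1); lane scale log-normal(σ = 0.1);
Poisson(10) negative-control background; a 4-fold positive ladder
(128…0.125 fM) at 150 counts/fM, high enough that the lowest probe
essentially never draws a zero (which would make the positive geometric
mean undefined); 2 planted unstable housekeeping genes. Treated samples
carry per-gene log₂ effects; singly-instilled treated animals are a 3/8
strong / 5/8 low-responder mixture with 0.25× attenuation for the low
responders, while four-weekly animals respond uniformly. Latent severity
rises with time for treated animals and stays 0 for vehicle; ordinal
lesion scores are a clipped discretized ramp of severity and percent
staining a logistic transform, each plus Gaussian latent noise
(σ = 0.3 default).

Not emulated: probe-level cross-hybridization, lane position effects
beyond the scalar lane scale, growth of the *number* of affected genes
over time (effects are constant in time unless restricted with
`effect_time_points`), tissue-specific effect profiles, and count-level
correlation between genes other than through shared severity. Passing
tests therefore demonstrate correctness of the statistical machinery
under the model's assumptions, not robustness to artifacts real panel
data may contain.

Effect-recovery and null-calibration experiments use responder fraction
1 (a uniform planted effect), since they quantify the calling rule's
operating characteristics, not the mixture.

## Orchestration

A run is a validated config (pydantic models, YAML-loadable): simulation
block or input paths, model choice, and the thresholds (q = 0.05,
|log₂| = 1, ρ = 0.5, edge = 0.7, inflation = 1.5) as overridable
defaults. The study splits into analysis units (tissue × experiment);
background, normalization, exclusion, pathway-Z and cell scores are per
unit, and contrasts never straddle units. The pipeline default of 2,000
confidence permutations (vs 10,000 for standalone use) keeps full-study
runs snappy without visibly changing the p-values at the thresholds that
matter. The manifest records package version, seed and a SHA-256 config
hash (output directory excluded — where results land is not part of what
they are); identical config + seed reruns are byte-identical.

## Problem sizes used in the acceptance script

Full study at the real panel size (770 + 40 + 6 + 8 probes, 120 lanes);
null calibration at 10,000 genes × 20 seeds; recovery at 2,000 genes
(10% DE) × 50 seeds; geNorm at 100 seeds; MCL at 50 planted graphs plus
20 random 15-node oracle comparisons; scoring bounds on 10,000 random
*t* vectors. These sizes give stable estimates (binomial SE on a 5%
rate at 200,000 tests is ~0.05 percentage points) while the whole script
completes in seconds to minutes on one CPU.
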