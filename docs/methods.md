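# Methods

This note documents the models and procedures `tmesig` implements, the
defaults and why, what the synthetic-data generators emulate (and do not),
and the numerical and design choices made where the design was genuinely
open.

## Data model

All expression matrices are genes × samples on the log2 scale; raw
quantifications must pass through `log2_transform(x, offset)` first.
Parsing is strict: duplicate gene or sample IDs, non-numeric cells and
missing values are errors. Missing-data imputation is deliberately out of
scope — a value that is absent stays absent, and the caller decides.

Probe-level arrays are collapsed to genes by keeping, per gene, the probe
with the highest mean expression (ties broken by lexicographically smallest
probe ID). This is a convention, chosen for determinism; collapsing by
highest mean favors the probe with the best signal but any single-probe rule
discards splice-level information.

Batch adjustment is a per-gene location–scale standardization: each batch is
centered to the gene's global mean and rescaled to the gene's global SD. It
removes additive and multiplicative batch effects exactly (each gene's
global mean is preserved to machine precision; a single batch is a no-op)
but performs no empirical-Bayes shrinkage across genes, so per-gene
estimates are noisier than ComBat-style adjustment on small batches. A gene
with zero variance inside a batch is centered only (warning).

## Signature construction

Within each dataset, every unordered pair of groups is compared by a
per-gene two-sample t-test (pooled variance; log-fold-change is the
difference of group means in log2 space). Candidates pass at raw p < 0.05
and |logFC| ≥ 1 — the gate uses the raw p-value, with BH q-values reported
per comparison for reference. A dataset's candidate set is the union over
its pairs; the signature is the exact intersection of candidate sets across
datasets, sorted. Union-within / intersection-across is the combination that
makes the signature mean "discriminates some pair of cell populations in
every dataset and is response-associated".

An optional moderated test squeezes per-gene variances toward a scaled
inverse-chi-square prior fitted by the method of moments on log s²
(trigamma relation inverted by bisection), adding the prior degrees of
freedom to the null t distribution. Both variants satisfy the same
antisymmetry and null-calibration properties; the plain pooled test is the
default because it has no fitted hyperparameters.

Genes with zero pooled variance get t = 0, p = 1 by convention (with a
warning) rather than an undefined statistic.

## Subtype discovery

Samples are clustered on z-scored signature genes (per-gene mean 0, SD 1,
ddof = 1; zero-variance genes dropped with a warning) by K-means, best of
`n_init` starts. The within-cluster dispersion W_k uses the pairwise form
Σ_r D_r/(2 n_r), computed through the algebraically identical sum of squared
distances to cluster means (the identity is asserted in the tests).

K-means runs on a canonical ordering of the samples (lexicographic by
feature vector) and cluster names follow first appearance in that order, so
the fit depends only on the data and the seed, never on column order.

The gap statistic draws B reference datasets uniformly over each feature's
observed range (simpler than a PCA-rotated box and adequate for z-scored
input), with Gap(k) = mean_b log W*_kb − log W_k and
se(k) = sd_b(log W*_kb)·√(1 + 1/B). Defaults: B = 50 reference draws,
n_init = 25, candidate k = 3..8.

Two selection rules are exposed. `global_max` takes the k maximizing Gap(k)
(smallest k on ties). `first_se_max` takes the smallest k with
Gap(k) ≥ Gap(k+1) − se(k+1). On tightly separated clusters the gap curve
flattens at the true k and the global maximum becomes a coin-flip between
the true k and larger values (differences of order 10⁻³, within simulation
noise) — the overestimation long documented for the plain maximum, and the
reason the SE criterion exists. The package therefore keeps `global_max` as
the literal default but uses and recommends `first_se_max` for recovery
evaluation; the full gap curve is always reported so the choice is
auditable. A fitted model warns when any cluster holds under 5% of samples,
the practical hint to prefer a smaller k on small cohorts.

New cohorts are assigned by z-scoring shared signature genes (≥80% coverage
required) and labeling each sample with the centroid of highest Pearson
correlation, ties to the smallest subtype index. `rescale=False` skips the
z-scoring for input already on the centroid scale; a sample with zero
variance across the shared genes has no defined correlation and is reported
by name. Independent clusterings are aligned by Hungarian assignment on the
contingency table, and all recovery assertions use the adjusted Rand index,
which is invariant to label permutation.

## Nearest-template prediction

A signed gene set becomes a template of +1 (up) and −1 (down) entries.
Expression is z-scored per gene across the cohort — any positive rescaling
of a gene is absorbed — and each sample is assigned to the template with the
smallest cosine distance between its template-gene vector and the template
(Pearson distance available; ties broken by template name so prediction is
independent of template order). The null redraws gene sets of the template's
size uniformly without replacement from the whole gene universe, carrying
the template's sign pattern; p = (#{null d ≤ observed d} + 1)/(B + 1), so
p ≥ 1/(B+1) and the test is valid by construction. Whenever C(G, g) ≤
10,000 the null is enumerated exhaustively and the permutation p equals the
brute-force value exactly. One RNG stream per (sample, template) derives
from the master seed, so results are reproducible under any execution
order. Calls are made at BH FDR < 0.2, computed across samples separately
per predicted template. Up to 20% of a template's genes may be absent from
the matrix (dropped with a warning), mirroring cross-platform application.

## Single-sample gene-set scores

Genes are ranked per sample (average ranks on ties; walk order breaks rank
ties by gene index for determinism). Walking down the ranking, in-set genes
add weight rank^τ normalized by the in-set total, out-of-set genes add
uniform 1/(N−m); the score is the summed running difference. τ defaults to
0.25, the originating method's convention; at τ = 0 the score is the plain
ECDF difference and equals an independent direct implementation to 1e-9
(asserted), and complementing the set negates the score exactly. Scores are
invariant to strictly increasing transforms of a sample's expression.

Range normalization divides a collection's scores by its global max − min,
so the extreme scores span exactly one unit; values then lie in [−1, 1]
whenever the collection spans zero, which holds for heterogeneous cohorts
since the statistic is centered. The immunotherapy-resistance flag applies
a strict > 0.35 cutoff to such normalized scores — the cutoff is
interpreted on the normalized scale (the source figure does not say; raw
scores are unbounded, so the normalized reading is the usable one).
Over-representation of a query gene list uses the one-sided hypergeometric
tail with BH correction across sets.

## TME composition

Marker scores are the arithmetic mean of log2 expression of a population's
markers — linear in marker shifts and independent of all other genes.
Deconvolution solves min ‖S f − b‖₂, f ≥ 0 per sample (Lawson–Hanson NNLS)
on the *linear* scale, because physical mixing of cell populations is
linear in linear space; the caller applies 2^x explicitly. Fractions are
renormalized to the simplex and the residual norm reported. NNLS is used
instead of kernelized ν-SVR deconvolution: it has no hyperparameters, is
exact on noiseless full-rank mixtures to machine precision, and accepts any
genes × cell-types signature matrix (full column rank required). The
package bundles no reference signature matrix; the simulators provide
identifiable synthetic ones.

## Survival and association statistics

Kaplan–Meier uses the product-limit estimator (ties grouped) with Greenwood
standard errors; with no censoring it equals the empirical survival
function. The log-rank test is the standard observed-minus-expected
chi-squared with df = groups − 1. Cox models maximize the partial
likelihood with Efron tie handling by default (less biased under ties;
Breslow available), Wald intervals and p-values; constant covariates and
models with more covariates than events are rejected, non-convergence is
flagged on the result, and |log HR| > 10 triggers a separation warning.

The recurrence-score calculator treats published coefficients as
configuration (gene groups with weights, reference genes, affine
calibration): rs = a + b·Σ w_g·(group mean − reference mean). Risk
categories: rs < 30 low, 30 ≤ rs ≤ 40 intermediate, rs > 40 high. The
printed category bounds overlap on (40, 41]; the calculator resolves the
overlap as intermediate up to and including 40 and high strictly above, so
the categories partition the line. A synthetic example configuration ships
in `examples/`; the published coefficients are not redistributed.

Categorical association uses Pearson chi-squared without continuity
correction (the convention asserted against a hand computation); an
optional fallback applies Fisher's exact test to 2×2 tables with any
expected count below 5, reporting which method ran. Kruskal–Wallis uses the
tie-corrected H with the chi-squared approximation; all-identical values
are an error rather than a zero-information statistic.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given a seed (streams keyed by stage
names) and return the planted truth consumed by the recovery tests.

- Sorted populations: per-gene baseline N(7, σ²) with disjoint marker sets
  elevated by a fixed log-fold-change in their own population; defaults
  (3 populations × 8 samples, effect 2.0, σ 0.3) mirror a small sorted-
  population array study.
- Response cohort: 9 responders vs 12 non-responders by default, matching
  the chemotherapy cohort size the signature derivation assumes; signal
  genes shifted by ±effect in responders with planted signs.
- Bulk cohort: per sample a latent subtype (uniform over k = 6), cell-type
  fractions from the subtype's Dirichlet, linear-space mixing of cell-type
  profiles built from disjoint high-expression marker blocks (log2 11 vs 6,
  making deconvolution identifiable by construction), subtype shifts
  (+2.0) on per-subtype signature genes, N(0, 0.3²) log-scale noise,
  exponential survival with per-subtype log-hazards (baseline rate
  log 2 / 24 months ⇒ median two years), uniform-before-event censoring at
  a fixed rate, and optional additive per-gene batch shifts.
- Abundance tables: log-normal taxa, subtype-enriched taxa multiplied by a
  fold-effect, columns renormalized to the simplex.

Noise is Gaussian on the log scale throughout; there is no count-level
(negative-binomial) simulation, no gene–gene correlation beyond the planted
structure, no platform or GC artifacts, and no single-cell droplet
features. Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative model, not robustness to every
artifact of real cohorts.

## Problem sizes used by the test suite and acceptance script

Chosen so the full suite and the acceptance run complete in a few minutes:
gene universes of 600–1000 genes, bulk cohorts of 120–300 samples,
B = 10–20 gap reference draws with n_init = 10 in tests (defaults are 50
and 25), 100–500 permutations for NTP, 100–200 replicates for calibration
checks. The acceptance script reports, for every quantity, the problem size
it used.

## Known limitations

- The location–scale batch adjustment does not pool information across
  genes; on very small batches ComBat-style shrinkage would be preferable.
- The gap statistic's uniform reference box ignores feature correlation; on
  strongly correlated signatures a PCA-aligned reference would be tighter.
- NNLS reports no per-sample empirical p-value and no absolute-abundance
  mode.
- The NTP distance and standardization are configurable conventions
  (cosine on cohort z-scores by default); the hosted tool this family of
  classifiers comes from does not publish its exact internals.
- Curated published panels (TGF-β response, exhausted T cells, MDSC, hot
  tumor, IFN-γ, immunotherapy-resistance) are not bundled for provenance
  reasons; the seven-gene EGFR ligand/receptor panel, which is public, is
  included, and the panel-file schema accepts any user-supplied GMT.
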