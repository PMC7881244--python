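# tmesig

Tumor-microenvironment-aware expression subtyping for bulk transcriptomic
cohorts.

Bulk tumor expression mixes signal from malignant cells with signal from the
non-malignant microenvironment (TME: immune, stromal and endothelial cells,
fibroblasts). `tmesig` implements, as a tested and reusable library, an
analysis that exploits this rather than fighting it: derive a gene signature
that discriminates *both* TME cell populations and chemotherapy response,
discover expression subtypes on that signature, and characterize the
subtypes by predicted drug response, TME composition, survival and
associated features. Intended users are computational biologists analyzing
colorectal-cancer-style expression cohorts, and methodologists who want each
stage as an importable, independently testable component.

## What it computes

- **Signature construction** — per-gene two-sample t-tests between every
  pair of groups within a dataset (sorted cell populations; responders vs
  non-responders), candidates gated at raw *p* < 0.05 and |log2 FC| ≥ 1,
  then the exact intersection of candidate sets across datasets.
- **Subtype discovery** — K-means on z-scored signature genes, with the
  number of clusters chosen by the gap statistic over k = 3..8:
  Gap(k) = E*[log W<sub>k</sub>] − log W<sub>k</sub>, reference data uniform
  over each feature's range; selection by global maximum or the
  one-standard-error rule. New cohorts are assigned to reference centroids
  by Pearson correlation.
- **Nearest-template prediction (NTP)** — each signed gene set becomes a
  ±1 template; a sample is assigned to the template with the smallest cosine
  distance on cohort-z-scored expression, with a permutation *p*-value from
  random gene sets of the same size (exhaustively enumerated when feasible)
  and calls at Benjamini–Hochberg FDR < 0.2.
- **Single-sample gene-set scores (ssGSEA)** — the summed running difference
  of weighted rank-ECDFs inside vs outside a set, per sample; range
  normalization across a collection; strict >0.35 flagging for
  immunotherapy-resistance style panels.
- **TME composition** — marker-mean abundance scores, and non-negative
  least-squares deconvolution of linear-scale bulk profiles against a
  cell-type signature matrix (fractions on the simplex).
- **Survival and associations** — Kaplan–Meier with Greenwood errors,
  log-rank, Cox proportional hazards (Efron or Breslow ties), a
  configuration-driven recurrence-score calculator with low/intermediate/
  high categories at 30 and 40, chi-squared / Fisher and Kruskal–Wallis
  association tests.
- **Synthetic cohorts** — generators for sorted-population, responder,
  bulk-mixture and taxon-abundance data with planted truth, used by every
  recovery test.

## Worked example

Discover subtypes on a synthetic bulk cohort with six planted subtypes
(`examples/03_discover_subtypes.py`):

```python
from sklearn.metrics import adjusted_rand_score
from tmesig import discover_subtypes, simulate_bulk_cohort

mx, ann, truth = simulate_bulk_cohort(n_samples=200, seed=2)
signature_genes = sorted(set().union(*truth.signature_genes.values()))
model = discover_subtypes(mx, signature_genes, k_range=range(3, 9),
                          b_refs=15, n_init=10, rule="first_se_max", seed=2)
print(model.gap_curve.to_frame().round(3).to_string(index=False))
print(f"selected k = {model.k} (planted k = 6)")
ari = adjusted_rand_score(truth.subtype_labels.to_numpy(), model.labels.to_numpy())
print(f"adjusted Rand index vs planted subtypes: {ari:.3f}")
```

prints

```
 k   gap    se  log_wk
 3 0.828 0.009   8.950
 4 1.122 0.009   8.641
 5 1.554 0.008   8.194
 6 2.337 0.009   7.398
 7 2.337 0.009   7.386
 8 2.335 0.010   7.378
selected k = 6 (planted k = 6)
adjusted Rand index vs planted subtypes: 1.000
```

The gap curve rises steeply until k = 6 and flattens there — within-cluster
dispersion stops improving beyond the planted structure — so the
one-standard-error rule selects k = 6, and the K-means labels reproduce the
planted subtypes exactly (ARI 1.0). The other stages are demonstrated the
same way in `examples/01…08`, and `tmesig report --outdir out --seed 0`
runs the whole sequence with pass/fail recovery checks.

## Command-line interface

`tmesig` exposes thin subcommands over the library: `simulate`,
`build-signature`, `cluster`, `ntp`, `score`, `deconvolve`, `survive`,
`associate` and `report`. Each writes TSV outputs plus a `manifest.json`
recording command, config hash, seed and file paths; exit codes are 0
(success), 2 (validation error), 3 (numeric failure).
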