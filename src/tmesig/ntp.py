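"""Nearest-template prediction with a random-gene-subsampling null.

Each signed gene set becomes a +/-1 template over its genes. Expression is
z-scored per gene across the cohort; each sample is assigned to the template
with the smallest cosine distance between the sample's template-gene vector
and the template. Significance comes from a null distribution built by
redrawing gene sets of the same size (carrying the template's sign pattern)
uniformly from the whole gene universe; whenever the universe is small
enough the null is enumerated exhaustively instead of sampled. P-values use
the +1 pseudo-count convention (p >= 1/(B+1), guaranteeing validity), and
calls are made at Benjamini-Hochberg FDR below a configurable threshold
(default 0.2), computed across samples separately for each predicted
template.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import spawn_rng
from .io import ExpressionMatrix, SignedGeneSet

__all__ = ["build_template", "ntp_classify", "benjamini_hochberg"]

EXHAUSTIVE_LIMIT = 10_000


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped at 1;
    always q >= p, monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_template(signed_set: SignedGeneSet) -> pd.Series:
    """+1 on up-genes, -1 on down-genes, indexed by gene (sorted)."""
    genes = sorted(signed_set.up_genes) + sorted(signed_set.down_genes)
    signs = [1.0] * len(signed_set.up_genes) + [-1.0] * len(signed_set.down_genes)
    return pd.Series(signs, index=genes, name=signed_set.name)


def _cosine_distance(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cosine distance of each row of ``rows`` to vector ``v`` (in [0, 2]).

    A zero-norm row is defined as orthogonal (distance 1).
    """
    num = rows @ v
    denom = np.linalg.norm(rows, axis=-1) * np.linalg.norm(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    return 1.0 - np.clip(cos, -1.0, 1.0)


def _pearson_distance(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=-1, keepdims=True)
    vc = v - v.mean()
    return _cosine_distance(rc, vc)


_METRICS = {"cosine": _cosine_distance, "pearson": _pearson_distance}


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def ntp_classify(
    matrix: ExpressionMatrix,
    templates: Sequence[SignedGeneSet],
    n_perm: int = 1000,
    fdr_cut: float = 0.2,
    seed: int = 0,
    metric: str = "cosine",
    min_coverage: float = 0.8,
    exhaustive: bool | str = "auto",
) -> pd.DataFrame:
    """Assign each sample to its nearest template and score significance.

    Returns one row per sample: ``sample_id``, ``template`` (nearest),
    ``distance``, ``p_value`` (permutation, +1 pseudo-count), ``fdr`` (BH
    across samples per predicted template) and ``significant``
    (fdr < ``fdr_cut``).

    The null redraws gene subsets of the template's size without replacement
    from the full gene universe, assigning the template's sign multiset to
    the drawn genes; one RNG stream per (sample, template) derived from
    ``seed`` keeps results reproducible under any execution order. With
    ``exhaustive="auto"`` the null enumerates all C(G, g) subsets whenever
    that count is at most 10,000 (then ``n_perm`` is ignored).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if not templates:
        raise ValueError("at least one template required")
    if exhaustive not in (True, False, "auto"):
        raise ValueError("exhaustive must be True, False or 'auto'")
    if exhaustive is not True and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    dist_fn = _METRICS[metric]

    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    G = len(gene_index)
    Z = _zscore_rows(matrix.values)  # genes x samples
    n_samples = matrix.n_samples

    # validate templates, drop missing genes (tolerated up to 1 - min_coverage)
    prepared: list[tuple[str, np.ndarray, np.ndarray]] = []  # name, rows, signs
    for t in sorted(templates, key=lambda t: t.name):
        tmpl = build_template(t)
        present = [g for g in tmpl.index if g in gene_index]
        if len(tmpl) > G:
            raise ValueError(f"template {t.name!r} larger than the gene universe")
        cov = len(present) / len(tmpl)
        if cov < min_coverage:
            raise ValueError(
                f"template {t.name!r}: only {cov:.0%} of its genes are in the "
                f"matrix (minimum {min_coverage:.0%})"
            )
        if len(present) < len(tmpl):
            warnings.warn(
                f"template {t.name!r}: dropping {len(tmpl) - len(present)} "
                "gene(s) absent from the matrix",
                stacklevel=2,
            )
        rows = np.array([gene_index[g] for g in present])
        signs = tmpl.loc[present].to_numpy()
        prepared.append((t.name, rows, signs))

    # observed distances: samples x templates
    obs = np.empty((n_samples, len(prepared)))
    for j, (_, rows, signs) in enumerate(prepared):
        obs[:, j] = dist_fn(Z[rows, :].T, signs)
    best = obs.argmin(axis=1)  # ties: first in name-sorted order

    records = []
    for i, sid in enumerate(matrix.sample_ids):
        name, rows, signs = prepared[best[i]]
        g = len(rows)
        d_obs = obs[i, best[i]]
        n_subsets = comb(G, g)
        use_exhaustive = exhaustive is True or (
            exhaustive == "auto" and n_subsets <= EXHAUSTIVE_LIMIT
        )
        if use_exhaustive:
            idx = np.fromiter(
                (j for c in combinations(range(G), g) for j in c), dtype=int
            ).reshape(n_subsets, g)
            null_d = dist_fn(Z[:, i][idx], signs)
            p = (np.count_nonzero(null_d <= d_obs) + 1) / (n_subsets + 1)
        else:
            rng = spawn_rng(seed, "ntp-null", sid, name)
            # B random g-subsets without replacement via partial argsort
            keys = rng.random((n_perm, G))
            idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
            null_d = dist_fn(Z[:, i][idx], signs)
            p = (np.count_nonzero(null_d <= d_obs) + 1) / (n_perm + 1)
        records.append((sid, name, float(d_obs), float(p)))

    out = pd.DataFrame(records, columns=["sample_id", "template", "distance", "p_value"])
    out["fdr"] = np.nan
    for name in out["template"].unique():
        mask = out["template"] == name
        out.loc[mask, "fdr"] = benjamini_hochberg(out.loc[mask, "p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_cut
    return out
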