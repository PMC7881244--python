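"""Derivation of the drug-resistance / microenvironment gene signature.

The signature is built in two steps: (1) within each contributing dataset,
per-gene two-sample t-tests between every pair of groups (sorted cell
populations, or responders vs non-responders), gating candidates at raw
p < 0.05 and |logFC| >= 1; (2) exact intersection of the per-dataset
candidate sets across datasets. Within a dataset the candidates from the
pairwise comparisons are combined by union.

logFC is the difference of group means in log2 space. BH q-values are
reported per comparison, but the candidate gate uses the raw p-value.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix
from .ntp import benjamini_hochberg

__all__ = [
    "differential_expression",
    "pairwise_population_de",
    "build_signature",
]


def _moderate_variance(sp2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes variance moderation by method of moments.

    Fits a scaled inverse-chi-square prior to the observed per-gene pooled
    variances (moments of log s^2, inverting the trigamma relation by
    bisection) and returns the posterior (squeezed) variances together with
    the prior degrees of freedom d0 (inf => all variances shrunk to the
    common value).
    """
    ok = sp2 > 0
    z = np.log(sp2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    rhs = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if not np.isfinite(rhs) or rhs <= 0:
        d0 = np.inf
        s02 = float(np.exp(ebar))
    else:
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid / 2.0) > rhs:
                lo = mid
            else:
                hi = mid
        d0 = float(np.sqrt(lo * hi))
        s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.where(ok, s02, 0.0)
    else:
        post = np.where(ok, (d0 * s02 + df * sp2) / (d0 + df), 0.0)
    return post, d0


def differential_expression(
    matrix: ExpressionMatrix,
    labels: pd.Series | Sequence[str],
    group_a: str,
    group_b: str,
    moderated: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test (group_a minus group_b).

    Pooled-variance t by default; ``moderated=True`` squeezes per-gene
    variances toward a moment-fitted prior (extra prior df added to the null
    t distribution). Genes with zero pooled variance get t = 0, p = 1 by
    convention (warning). Returns a DataFrame with columns gene_id, log_fc,
    t_stat, p_value, q_value (BH over all tested genes).
    """
    labels = pd.Series(list(labels), index=matrix.data.columns)
    ia = np.asarray(labels == group_a)
    ib = np.asarray(labels == group_b)
    na, nb = int(ia.sum()), int(ib.sum())
    if na < 2 or nb < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {group_a}: {na}, {group_b}: {nb})"
        )
    X = matrix.values
    A, B = X[:, ia], X[:, ib]
    lfc = A.mean(axis=1) - B.mean(axis=1)
    df = na + nb - 2
    sp2 = ((na - 1) * A.var(axis=1, ddof=1) + (nb - 1) * B.var(axis=1, ddof=1)) / df
    zero = sp2 <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} gene(s) with zero pooled variance: p set to 1",
            stacklevel=2,
        )
    if moderated:
        var_use, d0 = _moderate_variance(sp2, df)
        df_t = df + (d0 if np.isfinite(d0) else 1e9)
    else:
        var_use, df_t = sp2, df
    se = np.sqrt(var_use * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero | (se == 0), 0.0, lfc / np.where(se == 0, 1.0, se))
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df_t))
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log_fc": lfc,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )


def pairwise_population_de(
    matrix: ExpressionMatrix,
    population_labels: pd.Series | Sequence[str],
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    moderated: bool = False,
    return_tables: bool = False,
):
    """Candidate genes from all pairwise population comparisons.

    Runs :func:`differential_expression` for every unordered pair of
    populations (3 populations => 3 comparisons, 4 => 6) and returns the
    union of genes passing raw p < ``p_cut`` and |logFC| >= ``lfc_cut`` in at
    least one pair. With ``return_tables=True`` also returns the per-pair DE
    tables keyed by (group_a, group_b).
    """
    labels = pd.Series(list(population_labels), index=matrix.data.columns)
    pops = sorted(labels.unique())
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    genes: set[str] = set()
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in combinations(pops, 2):
        tab = differential_expression(matrix, labels, a, b, moderated=moderated)
        hits = tab[(tab["p_value"] < p_cut) & (tab["log_fc"].abs() >= lfc_cut)]
        genes |= set(hits["gene_id"])
        tables[(a, b)] = tab
    if return_tables:
        return genes, tables
    return genes


def build_signature(per_dataset_gene_sets: Sequence[Iterable[str]]) -> list[str]:
    """Exact intersection of per-dataset candidate gene sets, sorted.

    Requires at least two input sets. A disjoint input yields an empty
    signature (warning) — a valid, if useless, outcome.
    """
    sets = [set(s) for s in per_dataset_gene_sets]
    if len(sets) < 2:
        raise ValueError("build_signature needs candidate sets from >=2 datasets")
    out = set.intersection(*sets)
    if not out:
        warnings.warn("signature is empty: candidate sets do not overlap", stacklevel=2)
    return sorted(out)
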