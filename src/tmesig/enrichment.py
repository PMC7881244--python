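"""Single-sample gene-set scoring (ssGSEA), IPRES flagging, over-representation.

The per-sample score of a gene set is the summed running difference between
the weighted empirical cumulative distribution of expression ranks inside
the set and the uniform ECDF outside it: genes are ranked per sample
(descending expression, average ranks on ties); walking down the ranking,
in-set genes contribute steps proportional to rank^tau (normalized over the
in-set total) and out-of-set genes uniform steps; the score is the sum of
the in-minus-out difference over all positions. tau defaults to 0.25 (the
convention of the originating method); tau = 0 gives the plain ECDF
difference. Scores are rank-based, hence invariant to any strictly
increasing transform of a sample's expression.

"Range" normalization divides every score in a collection by the
collection's (max - min), so its extreme scores span exactly one unit; the
innate anti-PD1 resistance (IPRES) enrichment call applies a strict cutoff
(default 0.35) to such normalized scores.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignedGeneSet
from .ntp import benjamini_hochberg

__all__ = [
    "ssgsea_score",
    "score_panels",
    "flag_ipres",
    "hypergeometric_ora",
    "EGFR_LIGAND_RECEPTOR_PANEL",
]

# EGFR-pathway ligand/receptor panel (published seven-gene list)
EGFR_LIGAND_RECEPTOR_PANEL = frozenset(
    {"EGFR", "ERBB3", "EREG", "BTC", "HBEGF", "AREG", "IRS2"}
)


def _as_plain_sets(
    gene_sets: Mapping[str, Iterable[str]] | Sequence[SignedGeneSet],
) -> dict[str, tuple[set[str], set[str]]]:
    """Normalize input to name -> (up, down); plain sets have empty down."""
    out: dict[str, tuple[set[str], set[str]]] = {}
    if isinstance(gene_sets, Mapping):
        for name, genes in gene_sets.items():
            out[str(name)] = (set(genes), set())
    else:
        for s in gene_sets:
            out[s.name] = (set(s.up_genes), set(s.down_genes))
    if not out:
        raise ValueError("no gene sets supplied")
    return out


def _single_set_scores(
    ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, tau: float
) -> np.ndarray:
    """Scores of one gene set for all samples.

    ranks: genes x samples (average ranks, larger = higher expression);
    order: genes x samples argsort producing descending-rank walk order;
    in_set: boolean per gene.
    """
    n_genes, n_samples = ranks.shape
    m = int(in_set.sum())
    scores = np.empty(n_samples)
    for j in range(n_samples):
        oj = order[:, j]
        members = in_set[oj]
        w = ranks[oj, j] ** tau
        w_in = np.where(members, w, 0.0)
        ecdf_in = np.cumsum(w_in) / w_in.sum()
        ecdf_out = np.cumsum(~members) / (n_genes - m)
        scores[j] = float(np.sum(ecdf_in - ecdf_out))
    return scores


def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_sets: Mapping[str, Iterable[str]] | Sequence[SignedGeneSet],
    tau: float = 0.25,
    normalize: str = "raw",
) -> pd.DataFrame:
    """ssGSEA scores, samples x gene sets.

    ``gene_sets`` may be a name -> genes mapping or signed sets (a signed set
    with down-genes scores as score(up) - score(down)). Each set must cover
    at least one but not all matrix genes. ``normalize``: ``"raw"`` or
    ``"range"`` (divide the whole collection by max - min).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if normalize not in ("raw", "range"):
        raise ValueError(f"unknown normalization {normalize!r}")
    sets = _as_plain_sets(gene_sets)
    genes = matrix.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    X = matrix.values
    ranks = np.apply_along_axis(stats.rankdata, 0, X)  # average ranks, per sample
    # walk order: descending rank, gene index ascending on ties (deterministic)
    order = np.lexsort((np.arange(n_genes)[:, None] * np.ones_like(ranks), -ranks), axis=0)

    cols: dict[str, np.ndarray] = {}
    for name, (up, down) in sets.items():
        halves = []
        for half in (up, down):
            if not half:
                continue
            members = np.zeros(n_genes, dtype=bool)
            present = [gene_pos[g] for g in half if g in gene_pos]
            members[present] = True
            m = int(members.sum())
            if m == 0:
                raise ValueError(f"gene set {name!r} shares no genes with the matrix")
            if m == n_genes:
                raise ValueError(f"gene set {name!r} covers every gene in the matrix")
            halves.append(_single_set_scores(ranks, order, members, tau))
        cols[name] = halves[0] if len(halves) == 1 else halves[0] - halves[1]

    scores = pd.DataFrame(cols, index=matrix.sample_ids)
    if normalize == "range":
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span == 0:
            raise ValueError("cannot range-normalize a constant score collection")
        scores = scores / span
    return scores


def score_panels(
    matrix: ExpressionMatrix,
    panel_collection: Mapping[str, Iterable[str]] | Sequence[SignedGeneSet],
    tau: float = 0.25,
    normalize: str = "raw",
) -> pd.DataFrame:
    """Score a collection of TME/immunotherapy panels (delegates to ssGSEA)."""
    return ssgsea_score(matrix, panel_collection, tau=tau, normalize=normalize)


def flag_ipres(scores: pd.Series, cutoff: float = 0.35) -> pd.Series:
    """Per-sample IPRES-enriched flag: strictly score > cutoff.

    ``scores`` should be range-normalized ssGSEA values of the IPRES panel;
    a score exactly at the cutoff is *not* enriched.
    """
    return scores > cutoff


def hypergeometric_ora(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]] | Sequence[SignedGeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list.

    For each set: p = P(X >= overlap) with X ~ Hypergeom(|universe|,
    |set ∩ universe|, |query|); BH q-values across sets. Query genes outside
    the universe are an error.
    """
    uni = set(universe)
    query = set(query_genes)
    outside = query - uni
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:10]}")
    sets = _as_plain_sets(gene_sets)
    rows = []
    for name, (up, down) in sets.items():
        members = (up | down) & uni
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(query)))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
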