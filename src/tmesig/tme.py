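"""Tumor-microenvironment composition: marker scores and NNLS deconvolution.

Two complementary estimates of cell-population content in bulk expression:

- marker scores: per sample, the arithmetic mean of the log2 expression of a
  population's marker genes (the marker-counter convention) — a relative
  abundance proxy that needs no reference profiles;
- constrained deconvolution: per sample, non-negative least squares of the
  *linear-scale* bulk vector against a genes x cell-types signature matrix,
  fractions renormalized to the simplex. Mixing of cell populations is
  physical and therefore linear in linear space; the caller applies
  2**log2 - offset explicitly before deconvolving.

NNLS stands in for kernelized nu-SVR deconvolution: it needs no
hyperparameters, is exact on noiseless full-rank mixtures, and accepts any
user- or simulator-supplied signature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .enrichment import ssgsea_score
from .io import ExpressionMatrix

__all__ = [
    "SignatureMatrix",
    "DeconvolutionResult",
    "marker_population_score",
    "nnls_deconvolve",
    "stromal_fraction_score",
]


@dataclass
class SignatureMatrix:
    """Reference cell-type profiles, genes x cell types, linear scale."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("signature profiles must be non-negative (linear scale)")
        if self.profiles.index.duplicated().any() or self.profiles.columns.duplicated().any():
            raise ValueError("duplicate gene or cell-type IDs in signature matrix")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.profiles.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.profiles.columns]

    def is_full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.profiles.to_numpy()) == self.profiles.shape[1]


@dataclass
class DeconvolutionResult:
    """Per-sample cell-type fractions (simplex) and fit residuals."""

    fractions: pd.DataFrame  # samples x cell types, each row sums to 1
    residuals: pd.Series  # ||S f - b||_2 per sample (pre-normalization f)

    def __post_init__(self) -> None:
        F = self.fractions.to_numpy()
        if (F < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(F.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1 per sample")


def marker_population_score(
    matrix: ExpressionMatrix, marker_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Mean log2 expression of each population's markers, samples x populations.

    Markers absent from the matrix are ignored; a population whose marker set
    has no overlap with the matrix is an error.
    """
    if not marker_sets:
        raise ValueError("no marker sets supplied")
    cols = {}
    for pop, markers in marker_sets.items():
        present = [g for g in markers if g in matrix.data.index]
        if not present:
            raise ValueError(
                f"population {pop!r}: no marker gene present in the matrix"
            )
        cols[str(pop)] = matrix.data.loc[present].mean(axis=0)
    return pd.DataFrame(cols, index=matrix.data.columns)


def nnls_deconvolve(
    bulk_linear: pd.DataFrame | ExpressionMatrix, signature: SignatureMatrix
) -> DeconvolutionResult:
    """Non-negative least-squares deconvolution of linear-scale bulk profiles.

    Solves min ||S f - b||_2 s.t. f >= 0 per sample on the signature's genes,
    then renormalizes f to sum to 1. Requires linear-scale non-negative bulk
    values covering all signature genes, and a full-column-rank signature.
    """
    bulk = bulk_linear.data if isinstance(bulk_linear, ExpressionMatrix) else bulk_linear
    missing = [g for g in signature.genes if g not in bulk.index]
    if missing:
        raise ValueError(f"bulk matrix lacks signature genes: {missing[:10]}")
    if (bulk.to_numpy() < 0).any():
        raise ValueError("bulk values must be non-negative (linear scale expected)")
    if not signature.is_full_rank():
        raise ValueError("signature matrix is rank-deficient; cell types not separable")
    S = signature.profiles.to_numpy()
    B = bulk.loc[signature.genes].to_numpy()
    fracs = np.empty((B.shape[1], S.shape[1]))
    resid = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        f, r = nnls(S, B[:, j])
        total = f.sum()
        fracs[j] = f / total if total > 0 else np.full_like(f, 1.0 / len(f))
        resid[j] = r
    samples = [str(c) for c in bulk.columns]
    return DeconvolutionResult(
        fractions=pd.DataFrame(fracs, index=samples, columns=signature.cell_types),
        residuals=pd.Series(resid, index=samples, name="residual_norm"),
    )


def stromal_fraction_score(
    matrix: ExpressionMatrix, stromal_set: Iterable[str], tau: float = 0.25
) -> pd.Series:
    """Per-sample stromal-content score: ssGSEA of a stromal gene set."""
    stromal = set(stromal_set)
    if not stromal:
        raise ValueError("stromal gene set is empty")
    scores = ssgsea_score(matrix, {"stromal": stromal}, tau=tau)
    return scores["stromal"].rename("stromal_score")
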