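"""Expression subtype discovery: K-means on signature genes + gap statistic.

Samples are clustered on z-scored signature genes by K-means (best of
``n_init`` starts). The number of clusters is chosen by the gap statistic:
Gap(k) = mean_b log W*_kb - log W_k, where W_k is the within-cluster
dispersion (Tibshirani's pairwise-distance form, equal to the K-means SSE
for Euclidean distance) and the B reference datasets are drawn uniformly
over each feature's observed range. The default selection rule is the global
maximum of the gap curve over the candidate k values (3..8 by default); the
one-standard-error rule is available as an alternative.

K-means is run on a canonical ordering of the samples (lexicographic by
feature values), so results depend only on the data, not on column order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from ._seeds import spawn_rng
from .io import ExpressionMatrix

__all__ = [
    "GapCurve",
    "SubtypeModel",
    "KMeansFit",
    "zscore_genes",
    "kmeans_cluster",
    "within_dispersion",
    "pairwise_within_dispersion",
    "gap_statistic",
    "select_k",
    "discover_subtypes",
    "assign_to_reference",
    "align_cluster_labels",
]


@dataclass
class GapCurve:
    """Gap statistic curve over candidate cluster numbers."""

    k_values: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_wk: np.ndarray
    b_refs: int

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.gap = np.asarray(self.gap, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.log_wk = np.asarray(self.log_wk, dtype=float)
        n = len(self.k_values)
        if not (len(self.gap) == len(self.se) == len(self.log_wk) == n):
            raise ValueError("GapCurve arrays must have equal length")
        if self.b_refs < 10:
            raise ValueError("b_refs must be at least 10")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "gap": self.gap, "se": self.se, "log_wk": self.log_wk}
        )


@dataclass
class SubtypeModel:
    """A fitted subtype model: chosen k, centroids on the z-scored scale."""

    k: int
    signature_genes: list[str]
    centroids: pd.DataFrame  # k x genes
    labels: pd.Series  # per training sample, 1..k
    gap_curve: GapCurve | None
    seed: int

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k")
        lab = set(int(v) for v in self.labels)
        if not lab <= set(range(1, self.k + 1)):
            raise ValueError("labels must be in 1..k")

    def to_json(self, path) -> None:
        doc = {
            "k": self.k,
            "signature_genes": self.signature_genes,
            "centroids": self.centroids.to_dict(orient="split"),
            "labels": {str(s): int(v) for s, v in self.labels.items()},
            "gap_curve": None
            if self.gap_curve is None
            else {
                "k_values": self.gap_curve.k_values.tolist(),
                "gap": self.gap_curve.gap.tolist(),
                "se": self.gap_curve.se.tolist(),
                "log_wk": self.gap_curve.log_wk.tolist(),
                "b_refs": self.gap_curve.b_refs,
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            doc = json.load(fh)
        gc = doc["gap_curve"]
        return cls(
            k=doc["k"],
            signature_genes=doc["signature_genes"],
            centroids=pd.DataFrame(
                doc["centroids"]["data"],
                index=doc["centroids"]["index"],
                columns=doc["centroids"]["columns"],
            ),
            labels=pd.Series(doc["labels"]),
            gap_curve=None if gc is None else GapCurve(**gc),
            seed=doc["seed"],
        )


def zscore_genes(matrix: ExpressionMatrix, gene_list: Sequence[str]) -> ExpressionMatrix:
    """Restrict to ``gene_list`` and standardize each gene across samples.

    Missing genes are an error (all listed); zero-variance genes are dropped
    with a warning. Idempotent on already-standardized data.
    """
    missing = [g for g in gene_list if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    sub = matrix.data.loc[list(gene_list)]
    sd = sub.std(axis=1, ddof=1)
    dropped = sub.index[sd == 0].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance gene(s): {dropped}", stacklevel=2)
        sub = sub.loc[sd > 0]
        sd = sd[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, matrix.platform_note + " [z-scored]")


class KMeansFit(NamedTuple):
    labels: np.ndarray  # 1..k, aligned to sample order
    centroids: pd.DataFrame  # k x genes
    w_k: float  # within dispersion (pairwise form == SSE)


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W = sum_r D_r / (2 n_r) with D_r the total of pairwise squared
    distances inside cluster r — computed through the algebraically equal
    sum of squared distances to the cluster means."""
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def pairwise_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Literal pairwise form of the dispersion (O(n^2); used for checking)."""
    from scipy.spatial.distance import pdist

    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        if len(sub) > 1:
            w += float(pdist(sub, "sqeuclidean").sum()) / len(sub)
    return w


def _canonical_order(X: np.ndarray) -> np.ndarray:
    return np.lexsort(X.T[::-1])


def _fit_kmeans_points(X: np.ndarray, k: int, n_init: int, rng_int: int) -> np.ndarray:
    """K-means labels for points X (rows), invariant to row order."""
    order = _canonical_order(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_int)
    sorted_labels = km.fit_predict(X[order])
    # canonical cluster names: order of first appearance in canonical order
    remap: dict[int, int] = {}
    for lab in sorted_labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.empty(len(X), dtype=int)
    labels[order] = [remap[lab] for lab in sorted_labels]
    return labels


def kmeans_cluster(
    matrix: ExpressionMatrix, k: int, n_init: int = 25, seed: int = 0
) -> KMeansFit:
    """Best-of-``n_init`` K-means on samples (genes are features).

    Labels are 1..k, named by order of first appearance in the canonical
    sample ordering, so the fit is deterministic given the seed and invariant
    to sample order. Returns labels, centroids (cluster means) and the
    within-cluster dispersion W_k.
    """
    X = matrix.values.T  # samples x genes
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, n_samples={n}]")
    rng_int = int(spawn_rng(seed, "kmeans", k).integers(2**31 - 1))
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = _fit_kmeans_points(X, k, n_init, rng_int)
    cents = pd.DataFrame(
        [X[labels == lab].mean(axis=0) for lab in range(1, k + 1)],
        index=[f"centroid{lab}" for lab in range(1, k + 1)],
        columns=matrix.gene_ids,
    )
    return KMeansFit(labels, cents, within_dispersion(X, labels))


def gap_statistic(
    matrix: ExpressionMatrix,
    k_range: Sequence[int] = (3, 4, 5, 6, 7, 8),
    b_refs: int = 50,
    n_init: int = 25,
    seed: int = 0,
) -> GapCurve:
    """Gap statistic over ``k_range``.

    Reference datasets are drawn uniformly over each feature's observed
    range (B draws shared across k); se(k) = sd_b(log W*_kb) sqrt(1 + 1/B).
    """
    X = matrix.values.T
    n, p = X.shape
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, n_samples-1={n - 1}]")
    if b_refs < 10:
        raise ValueError("b_refs must be at least 10")
    mins, maxs = X.min(axis=0), X.max(axis=0)
    ref_rng = spawn_rng(seed, "gap-refs")
    refs = ref_rng.uniform(mins, maxs, size=(b_refs, n, p))

    log_wk, gap, se = [], [], []
    for k in ks:
        rng_obs = int(spawn_rng(seed, "gap-obs", k).integers(2**31 - 1))
        lw = np.log(within_dispersion(X, _fit_kmeans_points(X, k, n_init, rng_obs)))
        lstar = np.empty(b_refs)
        for b in range(b_refs):
            rng_ref = int(spawn_rng(seed, "gap-ref", k, b).integers(2**31 - 1))
            lab = _fit_kmeans_points(refs[b], k, n_init, rng_ref)
            lstar[b] = np.log(within_dispersion(refs[b], lab))
        log_wk.append(lw)
        gap.append(lstar.mean() - lw)
        se.append(lstar.std(ddof=0) * np.sqrt(1.0 + 1.0 / b_refs))
    return GapCurve(np.array(ks), np.array(gap), np.array(se), np.array(log_wk), b_refs)


def select_k(gap_curve: GapCurve, rule: str = "global_max") -> int:
    """Choose k from a gap curve.

    ``global_max``: the k maximizing Gap(k) (smallest k on ties).
    ``first_se_max``: the smallest k with Gap(k) >= Gap(k+1) - se(k+1)
    (falls back to the largest tested k when no k satisfies it).
    """
    if len(gap_curve.k_values) == 0:
        raise ValueError("empty gap curve")
    ks, g, s = gap_curve.k_values, gap_curve.gap, gap_curve.se
    if rule == "global_max":
        return int(ks[int(np.argmax(g))])  # argmax returns first (smallest k) on ties
    if rule == "first_se_max":
        for i in range(len(ks) - 1):
            if g[i] >= g[i + 1] - s[i + 1]:
                return int(ks[i])
        return int(ks[-1])
    raise ValueError(f"unknown rule {rule!r}")


def discover_subtypes(
    matrix: ExpressionMatrix,
    signature_genes: Sequence[str],
    k_range: Sequence[int] = (3, 4, 5, 6, 7, 8),
    b_refs: int = 50,
    n_init: int = 25,
    rule: str = "global_max",
    seed: int = 0,
    min_cluster_frac: float = 0.05,
) -> SubtypeModel:
    """Full discovery: z-score signature genes, gap statistic, final K-means.

    Warns when any resulting cluster holds under ``min_cluster_frac`` of the
    samples (a hint that a smaller k may be preferable on small cohorts).
    """
    z = zscore_genes(matrix, signature_genes)
    curve = gap_statistic(z, k_range=k_range, b_refs=b_refs, n_init=n_init, seed=seed)
    k = select_k(curve, rule=rule)
    fit = kmeans_cluster(z, k, n_init=n_init, seed=seed)
    sizes = pd.Series(fit.labels).value_counts()
    small = sizes[sizes < min_cluster_frac * z.n_samples]
    if len(small):
        warnings.warn(
            f"cluster(s) smaller than {min_cluster_frac:.0%} of samples: "
            f"{sorted(small.index)}",
            stacklevel=2,
        )
    return SubtypeModel(
        k=k,
        signature_genes=z.gene_ids,
        centroids=fit.centroids,
        labels=pd.Series(fit.labels, index=z.sample_ids, name="subtype"),
        gap_curve=curve,
        seed=seed,
    )


def assign_to_reference(
    new_matrix: ExpressionMatrix,
    model: SubtypeModel,
    min_coverage: float = 0.8,
    rescale: bool = True,
) -> pd.Series:
    """Label a new cohort by nearest reference centroid (Pearson r).

    The new cohort is z-scored on the genes shared with the model (set
    ``rescale=False`` when the matrix is already on the centroid scale);
    coverage of the model's signature genes below ``min_coverage`` is an
    error. Samples with zero variance across the shared genes (correlation
    undefined) raise an error naming them. Ties go to the smallest subtype
    index.
    """
    shared = [g for g in model.signature_genes if g in new_matrix.data.index]
    cov = len(shared) / len(model.signature_genes)
    if cov < min_coverage:
        raise ValueError(
            f"new matrix covers only {cov:.0%} of the model's signature genes "
            f"(minimum {min_coverage:.0%})"
        )
    sub = new_matrix.subset_genes(shared)
    if rescale:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = zscore_genes(sub, shared)
        shared = sub.gene_ids
    X = sub.values.T  # samples x genes
    C = model.centroids[shared].to_numpy()  # k x genes

    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    bad = [sid for sid, nz in zip(sub.sample_ids, xn) if nz == 0]
    if bad:
        raise ValueError(
            f"sample(s) with zero variance across signature genes "
            f"(correlation undefined): {bad}"
        )
    r = (Xc @ Cc.T) / np.outer(xn, np.where(cn == 0, 1.0, cn))
    labels = r.argmax(axis=1) + 1  # argmax takes the smallest index on ties
    return pd.Series(labels, index=sub.sample_ids, name="subtype")


def align_cluster_labels(
    labels_a: Sequence[int], labels_b: Sequence[int]
) -> dict[int, int]:
    """Permutation of ``labels_b``'s names maximizing agreement with
    ``labels_a`` (Hungarian assignment on the contingency table). Returns a
    mapping from b-labels to a-labels."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("labelings must cover the same samples")
    tab = pd.crosstab(b, a)
    rows, cols = linear_sum_assignment(-tab.to_numpy())
    return {int(tab.index[r]): int(tab.columns[c]) for r, c in zip(rows, cols)}
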