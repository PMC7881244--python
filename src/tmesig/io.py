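"""Core containers and I/O: expression matrices, annotations, signed gene sets.

All expression matrices in this package are genes x samples on log2 scale by
contract; raw RNA-seq quantifications must pass through :func:`log2_transform`
first. Parsing is strict: missing or non-numeric values are rejected (no
imputation — single-cell style imputation is deliberately out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "SignedGeneSet",
    "AnalysisConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_signed_gene_sets",
    "write_signed_gene_sets",
    "collapse_probes_to_genes",
    "adjust_batches",
    "log2_transform",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix (log2 scale by package contract).

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene (or probe)
    IDs and whose columns hold unique sample IDs. Values must be finite floats.
    """

    data: pd.DataFrame
    platform_note: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a pandas DataFrame")
        dup_g = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene IDs: {dup_g[:10]}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s[:10]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r} "
                "(missing values are not supported; imputation is out of scope)"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.platform_note)


@dataclass
class SampleAnnotation:
    """Per-sample annotations: group, batch, survival time/event, covariates.

    Wraps a DataFrame indexed by unique sample IDs. Whenever ``time`` is
    present for a sample, ``event`` must also be present (0/1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample IDs in annotation: {dup[:10]}")
        if "time" in self.table.columns:
            t = self.table["time"]
            if (t.dropna() < 0).any():
                raise ValueError("survival times must be non-negative")
            if "event" not in self.table.columns:
                raise ValueError("'event' column required whenever 'time' is present")
            ev = self.table.loc[t.notna(), "event"]
            if ev.isna().any():
                raise ValueError("event must be present for every sample with a time")
            if not set(ev.unique()) <= {0, 1, 0.0, 1.0, True, False}:
                raise ValueError("event must be coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"annotation column {name!r} not present")
        return self.table[name]


@dataclass(frozen=True)
class SignedGeneSet:
    """A named gene set split into up- and down-regulated members.

    ``down_genes`` may be empty (an unsigned set); the two halves are disjoint
    and their union non-empty. Signed sets serve as drug-response templates for
    nearest-template prediction and as scoring panels.
    """

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        both = self.up_genes & self.down_genes
        if both:
            raise ValueError(
                f"gene set {self.name!r}: genes in both UP and DN: {sorted(both)}"
            )
        if not (self.up_genes | self.down_genes):
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnalysisConfig:
    """Thresholds and sizes used across the pipeline.

    Defaults are the study constants: DE gate p < 0.05 with |logFC| >= 1,
    nearest-template significance at BH FDR < 0.2, IPRES enrichment at a
    normalized score > 0.35, and candidate cluster numbers k = 3..8.
    """

    de_p: float = 0.05
    de_lfc: float = 1.0
    ntp_fdr: float = 0.2
    ipres_cutoff: float = 0.35
    k_min: int = 3
    k_max: int = 8
    n_perm: int = 1000
    b_refs: int = 50
    n_init: int = 25
    seed: int = 0
    oncotype: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.de_p <= 1):
            raise ValueError("de_p must be in (0, 1]")
        if self.de_lfc < 0:
            raise ValueError("de_lfc must be non-negative")
        if not (0 < self.ntp_fdr <= 1):
            raise ValueError("ntp_fdr must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("require 2 <= k_min <= k_max")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.b_refs < 10:
            raise ValueError("b_refs must be at least 10")

    @property
    def k_range(self) -> tuple[int, int]:
        return (self.k_min, self.k_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Expression matrix I/O


def read_expression_matrix(
    path: str | Path, dialect: str = "strict", platform_note: str = ""
) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix.

    Layout: header row ``gene_id<TAB>sample1<TAB>...``; each following row is a
    gene ID and its numeric log2 values. ``dialect``:

    - ``"strict"``: duplicate gene rows are an error;
    - ``"collapse"``: duplicate gene rows are collapsed, keeping the row with
      the highest mean expression (first occurrence on a tie).

    Duplicate sample columns, a missing header, or any non-numeric/missing
    cell are always errors.
    """
    if dialect not in ("strict", "collapse"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line or "\t" not in header_line:
        raise ValueError(f"{path}: missing or malformed header row")
    header = header_line.split("\t")
    samples = header[1:]
    if any(s == "" for s in samples):
        raise ValueError(f"{path}: empty sample ID in header")
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"{path}: duplicate sample ID {s!r} in header")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = samples
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna() | df.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[gi]!r}, "
            f"sample {samples[si]!r} (strict numeric parsing; imputation refused)"
        )
    coerced.index = coerced.index.astype(str)

    if coerced.index.duplicated().any():
        dups = coerced.index[coerced.index.duplicated()].unique().tolist()
        if dialect == "strict":
            raise ValueError(f"{path}: duplicate gene rows: {dups[:10]}")
        keep_rows = []
        for g, grp in coerced.groupby(level=0, sort=False):
            means = grp.mean(axis=1).to_numpy()
            keep_rows.append(grp.iloc[int(np.argmax(means))])
        coerced = pd.DataFrame(keep_rows)
        coerced.index = [r.name for r in keep_rows]
    return ExpressionMatrix(coerced, platform_note=platform_note)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV layout read by :func:`read_expression_matrix`.

    Values are written with full repr precision so a round-trip is exact.
    """
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_annotations(path: str | Path) -> SampleAnnotation:
    """Read an annotation TSV (columns: sample_id, then free columns)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return SampleAnnotation(df)


def write_annotations(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT signed gene sets


def read_signed_gene_sets(path: str | Path) -> list[SignedGeneSet]:
    """Parse a GMT file into signed gene sets.

    Standard GMT lines are ``name<TAB>description<TAB>gene...``. Lines whose
    names pair as ``NAME_UP`` / ``NAME_DN`` merge into one signed set named
    ``NAME``; an unpaired line yields an up-only set. A gene appearing in both
    halves of the same set is an error.
    """
    raw: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in raw:
                raise ValueError(f"{path}: duplicate gene-set line {name!r}")
            raw[name] = genes
            order.append(name)

    out: dict[str, SignedGeneSet] = {}
    consumed: set[str] = set()
    for name in order:
        if name in consumed:
            continue
        if name.endswith("_UP") or name.endswith("_DN"):
            base = name[:-3]
            up = raw.get(base + "_UP", [])
            dn = raw.get(base + "_DN", [])
            consumed.update({base + "_UP", base + "_DN"} & set(raw))
            if base in out:
                raise ValueError(f"{path}: gene-set name {base!r} defined twice")
            out[base] = SignedGeneSet(base, frozenset(up), frozenset(dn))
        else:
            if name in out:
                raise ValueError(f"{path}: gene-set name {name!r} defined twice")
            out[name] = SignedGeneSet(name, frozenset(raw[name]))
            consumed.add(name)
    return list(out.values())


def write_signed_gene_sets(sets: Iterable[SignedGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            if s.down_genes:
                fh.write("\t".join([s.name + "_UP", "signed"] + sorted(s.up_genes)) + "\n")
                fh.write("\t".join([s.name + "_DN", "signed"] + sorted(s.down_genes)) + "\n")
            else:
                fh.write("\t".join([s.name, "unsigned"] + sorted(s.up_genes)) + "\n")


# ---------------------------------------------------------------------------
# Probe collapsing, batch adjustment, log transform


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    When several probes map to one gene, the probe with the highest mean
    expression is kept (ties broken by lexicographically smallest probe ID);
    probes without a mapping are dropped. Output genes are sorted.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene map is empty")
    rows: dict[str, tuple[float, str]] = {}
    means = matrix.data.mean(axis=1)
    for probe in matrix.gene_ids:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        cand = (-float(means[probe]), probe)
        if gene not in rows or cand < rows[gene]:
            rows[gene] = cand
    if not rows:
        raise ValueError("no probe in the matrix is covered by the map")
    genes = sorted(rows)
    data = pd.DataFrame(
        {g: matrix.data.loc[rows[g][1]] for g in genes}
    ).T
    data.columns = matrix.data.columns
    return ExpressionMatrix(data, matrix.platform_note)


def adjust_batches(
    matrix: ExpressionMatrix, batch_labels: Sequence[str] | pd.Series
) -> ExpressionMatrix:
    """Location-scale batch adjustment.

    Per gene, each batch is centered to the gene's global mean and scaled to
    the gene's global SD. This is a deliberate simplification of
    empirical-Bayes batch correction: it removes additive and multiplicative
    batch effects without shrinkage across genes. A gene with zero variance
    inside a batch is centered only (warning issued). Preserves each gene's
    global mean exactly; a single batch is a no-op.
    """
    labels = pd.Series(list(batch_labels), index=matrix.data.columns)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    X = matrix.data.to_numpy().copy()
    gmean = X.mean(axis=1, keepdims=True)
    gsd = X.std(axis=1, ddof=1, keepdims=True)
    warned = False
    for b in counts.index:
        cols = np.asarray(labels == b)
        sub = X[:, cols]
        bmean = sub.mean(axis=1, keepdims=True)
        bsd = sub.std(axis=1, ddof=1, keepdims=True)
        zero = (bsd[:, 0] == 0) | (gsd[:, 0] == 0)
        scale = np.where(zero[:, None], 1.0, np.divide(gsd, np.where(bsd == 0, 1.0, bsd)))
        X[:, cols] = (sub - bmean) * scale + gmean
        if zero.any() and not warned:
            warnings.warn(
                "zero-variance gene(s) within a batch: centered only, not rescaled",
                stacklevel=2,
            )
            warned = True
    return ExpressionMatrix(
        pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns),
        matrix.platform_note,
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + offset) for linear-scale (e.g. count/TPM) input."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    vals = matrix.data.to_numpy()
    if (vals < 0).any():
        raise ValueError("log2_transform requires non-negative input values")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(vals + offset), index=matrix.data.index, columns=matrix.data.columns
        ),
        matrix.platform_note + " [log2 transformed]",
    )
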