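"""Synthetic cohorts with planted truth.

Generates every input the analysis consumes, with the statistical structure
the method assumes:

- FACS-sorted cell-population expression sets with population-specific
  markers (three populations of eight samples each by default, mirroring a
  sorted-population array study);
- responder/non-responder drug cohorts (nine responders vs twelve
  non-responders by default) with signed response-associated genes;
- bulk tumor cohorts that are convex mixtures of cell-type profiles in
  linear space, carrying k latent expression subtypes, subtype-linked
  exponential survival hazards, optional batch shifts and Gaussian log-scale
  noise;
- taxon relative-abundance tables with subtype-enriched taxa.

Noise is Gaussian on the log2 scale throughout (the substrate data are
normalized arrays); no count-level simulation is attempted. Every generator
is fully deterministic given its seed and returns a :class:`SyntheticTruth`
bundle for downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import spawn_rng
from .io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "SyntheticTruth",
    "simulate_sorted_populations",
    "simulate_response_cohort",
    "simulate_bulk_cohort",
    "simulate_linear_mixtures",
    "simulate_abundance_table",
]

BASELINE_LOG2 = 7.0  # typical log2 array intensity for an expressed gene
MARKER_LOG2 = 11.0  # high-expression marker block level in cell-type profiles
BACKGROUND_LOG2 = 6.0  # off-marker level in cell-type profiles


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    seed: int
    population_labels: pd.Series | None = None
    subtype_labels: pd.Series | None = None
    response_labels: pd.Series | None = None
    mixing_fractions: pd.DataFrame | None = None
    marker_genes: dict[str, set[str]] = field(default_factory=dict)
    signature_genes: dict[str, set[str]] = field(default_factory=dict)
    signal_signs: dict[str, int] = field(default_factory=dict)
    survival_params: dict[str, float] = field(default_factory=dict)
    base_profiles: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        def ser(x):
            if isinstance(x, pd.Series):
                return {str(k): (int(v) if isinstance(v, (int, np.integer)) else v)
                        for k, v in x.items()}
            if isinstance(x, pd.DataFrame):
                return {c: x[c].round(10).tolist() for c in x.columns} | {
                    "_index": [str(i) for i in x.index]
                }
            return x

        return {
            "seed": self.seed,
            "population_labels": ser(self.population_labels),
            "subtype_labels": ser(self.subtype_labels),
            "response_labels": ser(self.response_labels),
            "mixing_fractions": ser(self.mixing_fractions),
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "signature_genes": {k: sorted(v) for k, v in self.signature_genes.items()},
            "signal_signs": dict(self.signal_signs),
            "survival_params": dict(self.survival_params),
        }


def simulate_sorted_populations(
    n_populations: int = 3,
    n_per_pop: int = 8,
    n_genes: int = 1000,
    n_markers_per_pop: int = 30,
    effect_lfc: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    marker_genes: Sequence[Sequence[str]] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """FACS-sorted cell-population expression sets.

    Each gene's baseline is N(7, noise_sd^2); each population's (disjoint)
    marker genes are elevated by ``effect_lfc`` in that population only, so
    every marker has a true |logFC| of ``effect_lfc`` against every other
    population. ``marker_genes`` may pin the marker sets explicitly (one
    sequence per population); otherwise they are drawn at random.
    """
    if effect_lfc < 0:
        raise ValueError("effect_lfc must be non-negative")
    genes = _gene_ids(n_genes)
    rng = spawn_rng(seed, "sorted-populations")

    if marker_genes is not None:
        if len(marker_genes) != n_populations:
            raise ValueError("marker_genes must supply one set per population")
        marker_lists = [list(m) for m in marker_genes]
        flat = [g for m in marker_lists for g in m]
        if len(set(flat)) != len(flat):
            raise ValueError("marker sets must be disjoint")
        unknown = set(flat) - set(genes)
        if unknown:
            raise ValueError(f"marker genes outside gene universe: {sorted(unknown)[:5]}")
    else:
        total = n_markers_per_pop * n_populations
        if total > n_genes:
            raise ValueError(
                f"{total} markers requested but only {n_genes} genes available"
            )
        picked = rng.choice(n_genes, size=total, replace=False)
        marker_lists = [
            [genes[j] for j in picked[i * n_markers_per_pop : (i + 1) * n_markers_per_pop]]
            for i in range(n_populations)
        ]

    pops = [f"pop{i + 1}" for i in range(n_populations)]
    samples = [f"{p}_s{j + 1}" for p in pops for j in range(n_per_pop)]
    labels = pd.Series(
        [p for p in pops for _ in range(n_per_pop)], index=samples, name="population"
    )
    X = rng.normal(BASELINE_LOG2, noise_sd, size=(n_genes, len(samples)))
    gidx = {g: i for i, g in enumerate(genes)}
    for p, mlist in zip(pops, marker_lists):
        cols = np.asarray(labels == p)
        rows = [gidx[g] for g in mlist]
        X[np.ix_(rows, cols)] += effect_lfc

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        platform_note=f"synthetic sorted populations (seed={seed})",
    )
    truth = SyntheticTruth(
        seed=seed,
        population_labels=labels,
        marker_genes={p: set(m) for p, m in zip(pops, marker_lists)},
    )
    return matrix, truth


def simulate_response_cohort(
    n_resp: int = 9,
    n_nonresp: int = 12,
    n_genes: int = 1000,
    n_signal_genes: int = 60,
    effect_lfc: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    signal_genes: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Responder / non-responder drug cohort.

    Default sizes (9 responders, 12 non-responders) match the chemotherapy
    cohort the signature derivation assumes. Signal genes are shifted by
    +effect_lfc or -effect_lfc in responders, with the planted sign recorded
    per gene in the truth bundle.
    """
    genes = _gene_ids(n_genes)
    rng = spawn_rng(seed, "response-cohort")
    if signal_genes is not None:
        sig = list(dict.fromkeys(signal_genes))
        unknown = set(sig) - set(genes)
        if unknown:
            raise ValueError(f"signal genes outside gene universe: {sorted(unknown)[:5]}")
    else:
        if n_signal_genes > n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        sig = [genes[j] for j in rng.choice(n_genes, size=n_signal_genes, replace=False)]

    samples = [f"resp_s{j + 1}" for j in range(n_resp)] + [
        f"nonresp_s{j + 1}" for j in range(n_nonresp)
    ]
    labels = pd.Series(
        ["responder"] * n_resp + ["nonresponder"] * n_nonresp,
        index=samples,
        name="response",
    )
    X = rng.normal(BASELINE_LOG2, noise_sd, size=(n_genes, len(samples)))
    signs = {g: int(s) for g, s in zip(sig, rng.choice([-1, 1], size=len(sig)))}
    gidx = {g: i for i, g in enumerate(genes)}
    resp_cols = np.asarray(labels == "responder")
    for g, s in signs.items():
        X[gidx[g], resp_cols] += s * effect_lfc

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        platform_note=f"synthetic response cohort (seed={seed})",
    )
    truth = SyntheticTruth(
        seed=seed,
        response_labels=labels,
        marker_genes={"response_signal": set(sig)},
        signal_signs=signs,
    )
    return matrix, truth


def simulate_bulk_cohort(
    k_subtypes: int = 6,
    n_samples: int = 300,
    n_genes: int = 1000,
    n_cell_types: int = 3,
    markers_per_cell_type: int = 40,
    signature_genes_per_subtype: int = 10,
    subtype_shift: float = 2.0,
    noise_sd: float = 0.3,
    dirichlet_alpha: np.ndarray | Sequence[Sequence[float]] | None = None,
    subtype_log_hazard: Sequence[float] | None = None,
    baseline_hazard: float = np.log(2) / 24.0,
    censor_rate: float = 0.3,
    batch_spec: Mapping[str, float] | None = None,
    subtype_signature_genes: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Bulk cohort = convex mixture of cell-type profiles + latent subtypes.

    Per sample: draw a subtype uniformly; draw cell-type fractions from that
    subtype's Dirichlet; mix the cell-type base profiles in *linear* space
    (mixing is physical, hence linear); return to log2; add the subtype's
    shift (+``subtype_shift``) on its signature genes and N(0, noise_sd^2)
    noise on every gene. Cell-type base profiles carry disjoint
    high-expression marker blocks (log2 11 vs background 6) so deconvolution
    identifiability holds by construction.

    Survival: time ~ Exponential(baseline_hazard * exp(log-hazard of the
    subtype)); an independent fraction ``censor_rate`` of samples is censored
    uniformly before its event. ``batch_spec`` (keys ``n_batches``,
    ``shift_mean``, ``shift_sd``) adds per-gene additive shifts drawn
    N(shift_mean, shift_sd^2) to every batch beyond the first.

    ``subtype_signature_genes`` may pin the per-subtype signature genes (e.g.
    to genes derived by the signature stage); they must avoid cell-type
    marker blocks.
    """
    if k_subtypes < 2:
        raise ValueError("k_subtypes must be >= 2")
    genes = _gene_ids(n_genes)
    n_marker = n_cell_types * markers_per_cell_type
    rng = spawn_rng(seed, "bulk-cohort")

    cell_types = [f"ct{c + 1}" for c in range(n_cell_types)]
    marker_blocks = {
        ct: set(genes[c * markers_per_cell_type : (c + 1) * markers_per_cell_type])
        for c, ct in enumerate(cell_types)
    }
    if subtype_signature_genes is not None:
        if len(subtype_signature_genes) != k_subtypes:
            raise ValueError("subtype_signature_genes must have one list per subtype")
        sig_lists = [list(s) for s in subtype_signature_genes]
        flat = [g for s in sig_lists for g in s]
        if len(flat) != len(set(flat)):
            raise ValueError("subtype signature gene lists must be disjoint")
        bad = set(flat) & set().union(*marker_blocks.values())
        if bad:
            raise ValueError(f"signature genes collide with cell-type markers: {sorted(bad)[:5]}")
        if set(flat) - set(genes):
            raise ValueError("subtype signature genes outside gene universe")
    else:
        need = n_marker + k_subtypes * signature_genes_per_subtype
        if need > n_genes:
            raise ValueError(f"need {need} genes for markers+signatures, have {n_genes}")
        sig_lists = [
            genes[
                n_marker + s * signature_genes_per_subtype :
                n_marker + (s + 1) * signature_genes_per_subtype
            ]
            for s in range(k_subtypes)
        ]

    if dirichlet_alpha is None:
        alpha = np.full((k_subtypes, n_cell_types), 2.0)
        for s in range(k_subtypes):
            alpha[s, s % n_cell_types] += 3.0
    else:
        alpha = np.asarray(dirichlet_alpha, dtype=float)
        if alpha.shape != (k_subtypes, n_cell_types):
            raise ValueError(
                f"dirichlet_alpha must be {k_subtypes} x {n_cell_types}, got {alpha.shape}"
            )
        if (alpha <= 0).any():
            raise ValueError("Dirichlet parameters must be positive")

    if subtype_log_hazard is None:
        loghaz = np.zeros(k_subtypes)
    else:
        loghaz = np.asarray(subtype_log_hazard, dtype=float)
        if loghaz.shape != (k_subtypes,):
            raise ValueError("subtype_log_hazard must have one value per subtype")

    # cell-type base profiles (log2) with disjoint marker blocks
    base_log2 = np.full((n_genes, n_cell_types), BACKGROUND_LOG2)
    for c, ct in enumerate(cell_types):
        rows = [genes.index(g) for g in sorted(marker_blocks[ct])]
        base_log2[rows, c] = MARKER_LOG2
    base_linear = 2.0 ** base_log2

    samples = [f"bulk_s{j + 1}" for j in range(n_samples)]
    subtypes = rng.integers(1, k_subtypes + 1, size=n_samples)
    fractions = np.vstack(
        [rng.dirichlet(alpha[s - 1]) for s in subtypes]
    )  # n_samples x n_cell_types
    bulk_linear = base_linear @ fractions.T  # genes x samples
    X = np.log2(bulk_linear)
    gidx = {g: i for i, g in enumerate(genes)}
    for s in range(1, k_subtypes + 1):
        cols = subtypes == s
        rows = [gidx[g] for g in sig_lists[s - 1]]
        X[np.ix_(rows, cols)] += subtype_shift
    X += rng.normal(0.0, noise_sd, size=X.shape)

    batches = pd.Series(["batch1"] * n_samples, index=samples, name="batch")
    if batch_spec is not None:
        nb = int(batch_spec.get("n_batches", 2))
        shift_mean = float(batch_spec.get("shift_mean", 2.0))
        shift_sd = float(batch_spec.get("shift_sd", 0.1))
        assign = rng.integers(0, nb, size=n_samples)
        batches = pd.Series([f"batch{b + 1}" for b in assign], index=samples, name="batch")
        for b in range(1, nb):
            shifts = rng.normal(shift_mean, shift_sd, size=n_genes)
            X[:, assign == b] += shifts[:, None]

    rates = baseline_hazard * np.exp(loghaz[subtypes - 1])
    event_times = rng.exponential(1.0 / rates)
    censored = rng.random(n_samples) < censor_rate
    obs_times = np.where(censored, rng.uniform(0, event_times), event_times)
    events = (~censored).astype(int)

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples),
        platform_note=f"synthetic bulk cohort (seed={seed})",
    )
    subtype_series = pd.Series(subtypes, index=samples, name="subtype")
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "group": subtype_series.astype(int),
                "batch": batches,
                "time": obs_times,
                "event": events,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        seed=seed,
        subtype_labels=subtype_series,
        mixing_fractions=pd.DataFrame(fractions, index=samples, columns=cell_types),
        marker_genes=marker_blocks,
        signature_genes={f"subtype{s + 1}": set(sig_lists[s]) for s in range(k_subtypes)},
        survival_params={
            **{f"log_hazard_subtype{s + 1}": float(loghaz[s]) for s in range(k_subtypes)},
            "baseline_hazard": float(baseline_hazard),
            "censor_rate": float(censor_rate),
        },
        base_profiles=pd.DataFrame(base_linear, index=genes, columns=cell_types),
    )
    return matrix, annotation, truth


def simulate_linear_mixtures(
    profiles: pd.DataFrame,
    n_samples: int = 100,
    alpha: Sequence[float] | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear-scale convex mixtures of the given cell-type profiles.

    ``profiles`` is genes x cell-types on linear scale. Fractions are drawn
    from a flat (or given) Dirichlet; multiplicative Gaussian noise with SD
    ``noise_frac`` x signal is applied per entry. Returns (bulk genes x
    samples, fractions samples x cell-types).
    """
    rng = spawn_rng(seed, "linear-mixtures")
    n_ct = profiles.shape[1]
    a = np.ones(n_ct) if alpha is None else np.asarray(alpha, float)
    F = rng.dirichlet(a, size=n_samples)  # n_samples x n_ct
    B = profiles.to_numpy() @ F.T
    if noise_frac > 0:
        B = np.clip(B * (1.0 + noise_frac * rng.standard_normal(B.shape)), 0.0, None)
    samples = [f"mix_s{j + 1}" for j in range(n_samples)]
    return (
        pd.DataFrame(B, index=profiles.index, columns=samples),
        pd.DataFrame(F, index=samples, columns=profiles.columns),
    )


def simulate_abundance_table(
    n_taxa: int,
    subtype_labels: pd.Series | Sequence[int],
    enriched_taxa_per_subtype: int = 3,
    effect: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Taxon relative-abundance table with subtype-enriched taxa.

    Abundances are log-normal (meanlog 0, sdlog 1); each subtype's enriched
    taxa are multiplied by ``effect`` in that subtype's samples; columns are
    renormalized to sum to 1. Returns (taxa x samples table, enriched-taxa
    map) — the map is the planted truth for recovery tests.
    """
    labels = pd.Series(subtype_labels)
    if labels.empty:
        raise ValueError("subtype_labels must be non-empty")
    if not isinstance(subtype_labels, pd.Series):
        labels.index = [f"ab_s{j + 1}" for j in range(len(labels))]
    uniq = sorted(labels.unique())
    need = enriched_taxa_per_subtype * len(uniq)
    if need > n_taxa:
        raise ValueError("not enough taxa for the requested enrichment structure")
    rng = spawn_rng(seed, "abundance")
    taxa = [f"taxon{i + 1:03d}" for i in range(n_taxa)]
    A = rng.lognormal(0.0, 1.0, size=(n_taxa, len(labels)))
    picked = rng.choice(n_taxa, size=need, replace=False)
    enriched: dict[str, set[str]] = {}
    for i, s in enumerate(uniq):
        rows = picked[i * enriched_taxa_per_subtype : (i + 1) * enriched_taxa_per_subtype]
        cols = np.asarray(labels == s)
        A[np.ix_(rows, cols)] *= effect
        enriched[str(s)] = {taxa[r] for r in rows}
    A /= A.sum(axis=0, keepdims=True)
    return pd.DataFrame(A, index=taxa, columns=labels.index), enriched
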