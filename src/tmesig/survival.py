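"""Survival analysis and subtype-feature association statistics.

Kaplan-Meier estimation and the log-rank test run through lifelines; Cox
proportional-hazards models run through statsmodels' partial-likelihood
implementation (Efron tie handling by default, Breslow available).
Categorical association uses Pearson's chi-squared without continuity
correction (optional Fisher fallback for sparse 2x2 tables), and abundance
differences across subtypes use the Kruskal-Wallis rank test with tie
correction. The recurrence-score calculator reproduces a weighted
gene-group expression score whose coefficients are supplied as
configuration, with risk categories low (< 30), intermediate (30..40) and
high (> 40); the published category bounds overlap at (40, 41], resolved
here as intermediate up to 40 and high strictly above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .io import ExpressionMatrix

__all__ = [
    "SurvivalCurve",
    "CoxFit",
    "kaplan_meier",
    "logrank_test",
    "cox_ph",
    "oncotype_dx",
    "chi_squared_association",
    "kruskal_wallis",
    "high_risk_binary",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray  # ascending, times with >= 1 observed event
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    greenwood_se: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, float)
        self.at_risk = np.asarray(self.at_risk, float)
        self.survival = np.asarray(self.survival, float)
        self.greenwood_se = np.asarray(self.greenwood_se, float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if ((self.survival < 0) | (self.survival > 1)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame  # index covariate: coef, hr, ci_lower, ci_upper, p
    ties_method: str
    converged: bool


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    if not set(np.unique(e)) <= {0.0, 1.0}:
        raise ValueError("events must be coded 0/1")
    return t, e.astype(int)


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    Tied times are grouped; with no events the curve is flat at 1 (empty
    event-time arrays).
    """
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter().fit(t, e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times_e = ev.index.to_numpy(float)
    at_risk = ev["at_risk"].to_numpy(float)
    d = ev["observed"].to_numpy(float)
    surv = np.array([kmf.predict(x) for x in times_e], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
    cum = np.cumsum(terms)
    se = np.where(np.isfinite(cum), surv * np.sqrt(np.where(np.isfinite(cum), cum, 0.0)), 0.0)
    se = np.where(surv == 0, 0.0, se)
    return SurvivalCurve(times_e, at_risk, surv, se)


def logrank_test(
    times: Sequence[float], events: Sequence[int], group_labels: Sequence
) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi2, df, p); df = #groups - 1."""
    t, e = _check_times_events(times, events)
    g = pd.Series(list(group_labels))
    k = g.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return float(res.test_statistic), k - 1, float(res.p_value)


def cox_ph(
    times: Sequence[float],
    events: Sequence[int],
    covariate_table: pd.DataFrame,
    ties: str = "efron",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards regression (partial likelihood).

    ``ties``: "efron" (default) or "breslow". Wald confidence intervals and
    p-values per covariate. Non-convergence is flagged on the result, not
    silently ignored; extreme coefficients (|log HR| > 10) trigger a
    separation warning.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _check_times_events(times, events)
    X = pd.DataFrame(covariate_table).astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    if int(e.sum()) < X.shape[1]:
        raise ValueError("fewer events than covariates; model not identifiable")

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = PHReg(t, X.to_numpy(), status=e, ties=ties)
        try:
            res = model.fit(disp=False)
        except Exception as err:  # noqa: BLE001 - surfaced as non-convergence
            raise RuntimeError(f"Cox fit failed: {err}") from err
        if any("onverge" in str(w.message) for w in caught):
            converged = False

    coef = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    z = stats.norm.ppf(1 - alpha / 2)
    if np.any(np.abs(coef) > 10):
        warnings.warn(
            "very large coefficient(s): possible separation / monotone likelihood",
            stacklevel=2,
        )
        converged = False
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p": 2 * stats.norm.sf(np.abs(coef) / se),
        },
        index=list(X.columns),
    )
    return CoxFit(summary=summary, ties_method=ties, converged=converged)


def oncotype_dx(matrix: ExpressionMatrix, weight_config: Mapping) -> pd.DataFrame:
    """Recurrence score and risk category per sample.

    ``weight_config`` supplies the published coefficients as data::

        reference_genes: [...]            # normalization genes
        groups: {name: {genes: [...], weight: w}, ...}
        intercept: a                      # affine calibration
        slope: b

    Per sample: each gene group's mean log2 expression is normalized by
    subtracting the reference-gene mean; rs = a + b * sum_g w_g * group_g.
    Categories: rs < 30 low, 30 <= rs <= 40 intermediate, rs > 40 high (the
    overlapping printed bounds at (40, 41] are resolved to high).
    """
    ref_genes = list(weight_config["reference_genes"])
    groups = weight_config["groups"]
    intercept = float(weight_config.get("intercept", 0.0))
    slope = float(weight_config.get("slope", 1.0))
    needed = set(ref_genes) | {g for grp in groups.values() for g in grp["genes"]}
    missing = sorted(needed - set(matrix.gene_ids))
    if missing:
        raise ValueError(f"matrix lacks required genes: {missing[:10]}")

    ref = matrix.data.loc[ref_genes].mean(axis=0)
    rs = pd.Series(intercept, index=matrix.data.columns, dtype=float)
    for grp in groups.values():
        gmean = matrix.data.loc[list(grp["genes"])].mean(axis=0)
        rs = rs + slope * float(grp["weight"]) * (gmean - ref)
    category = pd.cut(
        rs,
        bins=[-np.inf, 30, 40, np.inf],
        right=False,
        labels=["low", "intermediate", "high"],
    ).astype(str)
    # pd.cut with right=False puts exactly 40 into the high bin; the resolved
    # rule keeps rs == 40 intermediate, so fix the boundary explicitly.
    category[rs == 40] = "intermediate"
    out = pd.DataFrame({"rs": rs, "category": category})
    out.index.name = "sample_id"
    return out


def chi_squared_association(
    contingency_table: np.ndarray | pd.DataFrame, fallback_fisher: bool = False
) -> tuple[float, float, str]:
    """Pearson chi-squared test of independence (no continuity correction).

    With ``fallback_fisher=True``, a 2x2 table with any expected count < 5 is
    tested by Fisher's exact test instead; returns (statistic, p, method)
    where method is "chi2" or "fisher" (statistic is the odds ratio there).
    Zero row/column margins are an error.
    """
    tab = np.asarray(contingency_table, float)
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("contingency table must hold non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
    if fallback_fisher and tab.shape == (2, 2) and (expected < 5).any():
        odds, p_f = stats.fisher_exact(tab.astype(int), alternative="two-sided")
        return float(odds), float(p_f), "fisher"
    return float(chi2), float(p), "chi2"


def kruskal_wallis(
    values: Sequence[float], group_labels: Sequence
) -> tuple[float, float]:
    """Kruskal-Wallis rank test (tie-corrected H, chi-squared p)."""
    v = np.asarray(values, float)
    g = pd.Series(list(group_labels))
    if g.nunique() < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if len(np.unique(v)) < 2:
        raise ValueError("all values identical: Kruskal-Wallis undefined")
    samples = [v[np.asarray(g == lev)] for lev in g.unique()]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def high_risk_binary(labels: Sequence, high_risk: Iterable) -> pd.Series:
    """Merge the given subtype labels into a single "high" group vs "other"."""
    high = set(high_risk)
    s = pd.Series(list(labels))
    return s.map(lambda x: "high" if x in high else "other").rename("risk_group")
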