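"""Survival estimation and the study's inferential statistics.

Kaplan-Meier product-limit curves and the unweighted log-rank test are
implemented directly (the product-limit recursion is a dozen lines and
keeping it in-package makes the large null-calibration simulations cheap);
multiple-testing correction, Pearson inference and the chi-square test are
delegated to statsmodels / scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xsub.errors import XsubError

__all__ = [
    "TestResult",
    "km_estimate",
    "logrank_test",
    "fisher_rz_compare",
    "pearson_with_p",
    "bh_adjust",
    "chisq_2x2",
    "incidence_summary",
    "delta_ct_expression",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test: statistic, two-sided p, df/n, method label."""

    statistic: float
    p_value: float
    df: float | None
    method: str


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one group.

    Parameters
    ----------
    times, events
        Follow-up time (>= 0) and event flag per subject.  At tied times,
        deaths are processed before censorings (standard product-limit
        convention), i.e. a subject censored at t is still at risk for the
        deaths at t.

    Returns
    -------
    DataFrame indexed by distinct event time with columns ``at_risk``,
    ``events``, ``censored`` and ``survival``.  S(0) = 1 is implicit; the
    curve is non-increasing and censoring alone produces no step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise XsubError("km_estimate: no records")
    if (times < 0).any():
        raise XsubError("km_estimate: negative survival time")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    n = times.size

    rows = []
    surv = 1.0
    for t in distinct:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        c = int(np.sum((times == t) & ~events))
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append((t, at_risk, d, c, surv))
    km = pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "survival"])
    return km.set_index("time")


def logrank_test(times, events, groups) -> TestResult:
    """Unweighted k-sample log-rank test.

    Chi-square statistic with k-1 degrees of freedom, computed from the
    observed-minus-expected event counts and the hypergeometric
    variance-covariance at each distinct event time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if not (times.size == events.size == groups.size):
        raise XsubError("logrank_test: times, events and groups must have equal length")
    if not events.any():
        raise XsubError("logrank_test: no events observed")
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise XsubError("logrank_test: need >=2 groups")

    group_idx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events])

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk_mask = times >= t
        n_j = np.bincount(group_idx[at_risk_mask], minlength=k).astype(float)
        n_tot = n_j.sum()
        d_mask = (times == t) & events
        d_j = np.bincount(group_idx[d_mask], minlength=k).astype(float)
        d_tot = d_j.sum()
        observed += d_j
        expected += d_tot * n_j / n_tot
        if n_tot > 1:
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            cov += factor * (np.diag(n_j) * n_tot - np.outer(n_j, n_j)) / n_tot**2

    u = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(v) @ u)
    p = float(stats.chi2.sf(stat, k - 1))
    return TestResult(statistic=stat, p_value=p, df=k - 1, method="log-rank")


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise XsubError(f"fisher_rz_compare: |r| must be < 1, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise XsubError(f"fisher_rz_compare: need n >= 4, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p_value=p, df=None, method="fisher-r-to-z")


def pearson_with_p(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise XsubError("pearson_with_p: need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise XsubError("pearson_with_p: zero variance input")
    res = stats.pearsonr(x, y)
    p = max(float(res.pvalue), 1e-300)
    return TestResult(statistic=float(res.statistic), p_value=p, df=x.size - 2, method="pearson")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise XsubError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Two-sided chi-square test on a 2x2 table, no continuity correction by default."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise XsubError("chisq_2x2: counts must be non-negative")
    if table.sum() == 0:
        raise XsubError("chisq_2x2: empty table")
    stat, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(stat), p_value=float(p), df=df, method="chi-square")


def _has_site(sites, site: str) -> bool:
    if isinstance(sites, str):
        sites = {s for s in sites.split(";") if s}
    if site == "any":
        return len(sites) > 0
    return site in sites


def incidence_summary(cohort: pd.DataFrame, site: str = "any") -> pd.DataFrame:
    """Per-genotype metastasis incidence at a site (or ``"any"`` site).

    Returns one row per genotype with ``affected``, ``total``, ``percent``
    (exact) and ``percent_rounded`` (nearest integer, the style used in
    incidence figures).
    """
    if "genotype" not in cohort.columns or "sites" not in cohort.columns:
        raise XsubError("incidence_summary: cohort needs 'genotype' and 'sites' columns")
    rows = []
    for genotype, sub in cohort.groupby("genotype", sort=True):
        total = len(sub)
        if total == 0:
            raise XsubError(f"incidence_summary: genotype {genotype!r} has no animals")
        affected = int(sum(_has_site(s, site) for s in sub["sites"]))
        pct = 100.0 * affected / total
        rows.append((genotype, affected, total, pct, round(pct)))
    return pd.DataFrame(
        rows, columns=["genotype", "affected", "total", "percent", "percent_rounded"]
    ).set_index("genotype")


def delta_ct_expression(ct_target, ct_reference):
    """Relative qPCR expression: 2^-(CT_target - CT_reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise XsubError("delta_ct_expression: CT values must be finite")
    out = 2.0 ** (-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out
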