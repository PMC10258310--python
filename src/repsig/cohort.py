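"""Cohort-level statistics: rank tests, frequency summaries, survival.

Group comparisons use the Wilcoxon signed-rank test (paired) and the
Mann-Whitney U test (independent), both two-sided, with exact p-values by
full enumeration for small samples (the regime where the normal
approximation is poorest) and a tie- and continuity-corrected normal
approximation otherwise. Correlations are Spearman rank correlations.
Categorical tables use Fisher's exact test (2x2, two-sided by the
point-probability rule) when any expected cell is below 5, else Pearson's
chi-square without continuity correction. Survival stratification
dichotomizes a repertoire feature at the cohort median and compares
Kaplan-Meier curves with the two-group log-rank test.

Exact enumeration thresholds: signed-rank enumerates all 2^n sign
assignments for n <= 12 non-zero differences; Mann-Whitney enumerates all
C(n_a + n_b, n_a) rank splits for n_a + n_b <= 12. Both operate on midranks
so ties are handled identically in the exact and approximate branches.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

EXACT_N_MAX = 12  # full enumeration up to this many (non-zero / combined) values


class UndefinedTestError(ValueError):
    """The requested test is undefined on the given input (e.g. all ties)."""


@dataclass(slots=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    q_value: float | None = None
    estimate: float | None = None  # e.g. Spearman rho


@dataclass(slots=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one stratum."""

    group_label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _two_sided_from_distribution(observed: float, distribution: np.ndarray) -> float:
    """Two-sided exact p: 2 * min(P(T <= t), P(T >= t)), capped at 1."""
    eps = 1e-9
    lo = float(np.mean(distribution <= observed + eps))
    hi = float(np.mean(distribution >= observed - eps))
    return min(1.0, 2.0 * min(lo, hi))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float] | None = None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; ties among |differences| receive average
    ranks. The statistic is W+, the sum of ranks of positive differences.
    Exact p by enumeration of all sign assignments for n <= 12, else a
    normal approximation with tie correction and 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        d = x - y
    else:
        d = x
    mask = ~np.isnan(d)
    d = d[mask]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    if n < 3:
        raise UndefinedTestError(f"need >= 3 non-zero differences, got {n}")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        # distribution of W+ over all 2^n sign assignments of the observed ranks
        signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
        dist = signs @ ranks
        p = _two_sided_from_distribution(w_plus, dist)
        method = "wilcoxon_signed_rank_exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        if var <= 0:
            raise UndefinedTestError("zero variance (all differences tied)")
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "wilcoxon_signed_rank_normal"
    return TestResult(statistic=w_plus, p_value=min(p, 1.0), n=n, method=method)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    U is computed for the first sample from midranks. Exact p by enumeration
    of all rank splits for n_a + n_b <= 12, else a tie-corrected normal
    approximation with 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise UndefinedTestError(f"each group needs >= 2 values, got {na} and {nb}")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    n = na + nb

    if n <= EXACT_N_MAX:
        dist = np.array(
            [
                sum(ranks[list(idx)]) - na * (na + 1) / 2.0
                for idx in itertools.combinations(range(n), na)
            ]
        )
        p = _two_sided_from_distribution(u_a, dist)
        method = "mann_whitney_exact"
    else:
        mean = na * nb / 2.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            raise UndefinedTestError("zero variance (all values tied)")
        z = (u_a - mean - 0.5 * np.sign(u_a - mean)) / math.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "mann_whitney_normal"
    return TestResult(statistic=u_a, p_value=min(p, 1.0), n=n, method=method)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (Pearson on midranks, t-approximation p).

    Pairs with a missing value are dropped; a constant vector leaves the
    correlation undefined (rho reported as NaN, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise UndefinedTestError(f"need >= 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        import warnings

        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return TestResult(statistic=np.nan, p_value=1.0, n=n, method="spearman", estimate=np.nan)
    rho, p = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(rho), p_value=float(p), n=n, method="spearman", estimate=float(rho)
    )


def frequency_table(
    data: pd.DataFrame | Sequence,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per categorical variable (cohort summary).

    Accepts a DataFrame or a sequence of :class:`~repsig.io.ClinicalRecord`.
    Percent = 100 * count / total rows, rounded to 1 decimal. Returns a tidy
    frame with columns (variable, category, count, percent).
    """
    if not isinstance(data, pd.DataFrame):
        from .io import clinical_frame

        data = clinical_frame(list(data)).reset_index(drop=True)
    if len(data) == 0:
        raise UndefinedTestError("frequency table of an empty cohort")
    if variables is None:
        variables = [
            c for c in data.columns if data[c].dtype == object and c != "patient_id"
        ]
    total = len(data)
    rows = []
    for var in variables:
        counts = data[var].value_counts(dropna=False)
        for category, count in counts.items():
            rows.append(
                {
                    "variable": var,
                    "category": category,
                    "count": int(count),
                    "percent": round(100.0 * count / total, 1),
                }
            )
    return pd.DataFrame(rows)


def categorical_test(
    table: Sequence[Sequence[int]],
    method: str = "auto",
) -> TestResult:
    """Fisher's exact test (2x2, small expected counts) or Pearson chi-square.

    With ``method="auto"``, uses Fisher's exact two-sided test
    (point-probability rule, the R convention) for a 2x2 table with any
    expected cell below 5, otherwise Pearson's chi-square without continuity
    correction; larger-than-2x2 tables always use chi-square. Pass
    ``method="fisher"`` or ``"chi2"`` to force a branch.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must be a 2-D array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise UndefinedTestError("contingency table has a zero margin")
    n = int(t.sum())
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    use_fisher = method == "fisher" or (
        method == "auto" and t.shape == (2, 2) and (expected < 5).any()
    )
    if use_fisher:
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test is implemented for 2x2 tables only")
        odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult(statistic=float(odds), p_value=float(p), n=n, method="fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), n=n, method="chi_square")


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def km_curve(
    durations: Sequence[float],
    events: Sequence[int],
    label: str = "",
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, label=label or None)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    )
    return SurvivalCurve(
        group_label=label,
        times=times,
        survival=surv,
        at_risk=at_risk.astype(int),
        n=int(durations.size),
        n_events=int(events.sum()),
    )


def median_split(values: Sequence[float]) -> np.ndarray:
    """Dichotomize at the median: True = high (> median), ties go to low."""
    v = np.asarray(values, dtype=float)
    return v > np.nanmedian(v)


def km_logrank(
    cohort: pd.DataFrame,
    feature: str,
    endpoint: str = "OS",
) -> tuple[SurvivalCurve, SurvivalCurve, TestResult]:
    """Median-split survival stratification with a two-group log-rank test.

    ``cohort`` must carry ``{endpoint}_months`` and ``{endpoint}_event``
    columns (endpoint one of PFS, RFS, OS) plus the numeric ``feature``.
    Patients at or below the cohort median form the "low" group. When no
    events are observed the log-rank test is undefined (p = NaN) but both
    curves are still returned.
    """
    endpoint = endpoint.upper()
    if endpoint not in {"PFS", "RFS", "OS"}:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    tcol, ecol = f"{endpoint.lower()}_months", f"{endpoint.lower()}_event"
    for col in (tcol, ecol, feature):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks column {col!r}")
    df = cohort[[feature, tcol, ecol]].dropna()
    if len(df) < 4:
        raise UndefinedTestError(f"too few complete rows ({len(df)}) for {feature}/{endpoint}")
    high = median_split(df[feature].to_numpy())
    low_curve = km_curve(df.loc[~high, tcol], df.loc[~high, ecol], label=f"{feature}_low")
    high_curve = km_curve(df.loc[high, tcol], df.loc[high, ecol], label=f"{feature}_high")
    n_events = int(df[ecol].sum())
    if n_events < 2 or (~high).sum() == 0 or high.sum() == 0:
        test = TestResult(statistic=np.nan, p_value=np.nan, n=len(df), method="logrank")
    else:
        res = logrank_test(
            df.loc[~high, tcol],
            df.loc[high, tcol],
            event_observed_A=df.loc[~high, ecol],
            event_observed_B=df.loc[high, ecol],
        )
        test = TestResult(
            statistic=float(res.test_statistic),
            p_value=float(res.p_value),
            n=len(df),
            method="logrank",
        )
    return low_curve, high_curve, test


def survival_curve_frame(curves: Sequence[SurvivalCurve]) -> pd.DataFrame:
    """Tidy long-format table of Kaplan-Meier curves for export."""
    rows = []
    for c in curves:
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append(
                {
                    "group": c.group_label,
                    "time": float(t),
                    "survival": float(s),
                    "at_risk": int(r),
                }
            )
    return pd.DataFrame(rows)
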