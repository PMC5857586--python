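"""Group-level statistics: t-tests, pairwise-complete Pearson correlations,
skewness, variable orientation and cohort classification tables.

Conventions follow the analysis this package reproduces: two-sided p-values
throughout, no multiple-testing correction, pooled-variance two-sample t-tests
(df = n1 + n2 - 2; Welch available behind a flag), pairwise deletion for
correlations so each cell reports its own n, and — before correlating — all
variables oriented so that higher values mean better performance (prediction
and reach latencies are negated; the dilation difference already points that
way).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

#: Sign applied to each summary measure so that "better" is positive.
ORIENTATIONS: Mapping[str, int] = {
    "prediction_latency_ms": -1,
    "reach_latency_s": -1,
    "dilation_difference_mm": 1,
    "vineland_motor": 1,
}


def orient_variables(summary: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flip signs so high performance is positive; returns (table, sign map)."""
    out = summary.copy()
    applied = {}
    for col, sign in ORIENTATIONS.items():
        if col in out.columns:
            out[col] = sign * out[col]
            applied[col] = sign
    return out, applied


@dataclass(frozen=True)
class TTestResult:
    kind: str  # one_sample | paired | two_sample
    t: float
    df: float
    p: float
    mean: float
    se: float


def _finite(values: Iterable[float]) -> np.ndarray:
    a = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, float)
    return a[np.isfinite(a)]


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> TTestResult:
    """t = (mean - mu) / (sd / sqrt(n)), df = n - 1, two-sided p."""
    a = _finite(values)
    if len(a) < 2:
        raise ValidationError("one-sample t-test requires n >= 2")
    sd = float(np.std(a, ddof=1))
    if sd == 0.0:
        raise ValidationError("one-sample t-test undefined for zero-variance data")
    res = sps.ttest_1samp(a, popmean=mu)
    se = sd / np.sqrt(len(a))
    return TTestResult("one_sample", float(res.statistic), float(res.df), float(res.pvalue),
                       float(np.mean(a)), se)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """One-sample t-test on paired differences after pairwise deletion."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if len(xa) != len(ya):
        raise ValidationError("paired t-test requires equal-length vectors")
    ok = np.isfinite(xa) & np.isfinite(ya)
    if ok.sum() < 2:
        raise ValidationError("paired t-test requires at least 2 complete pairs")
    r = one_sample_t(xa[ok] - ya[ok], mu=0.0)
    return TTestResult("paired", r.t, r.df, r.p, r.mean, r.se)


def two_sample_t(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled-variance by default (df = n1 + n2 - 2)."""
    aa, bb = _finite(a), _finite(b)
    if len(aa) < 2 or len(bb) < 2:
        raise ValidationError("two-sample t-test requires n >= 2 per group")
    if np.std(aa, ddof=1) == 0.0 and np.std(bb, ddof=1) == 0.0:
        raise ValidationError("two-sample t-test undefined: both groups constant")
    res = sps.ttest_ind(aa, bb, equal_var=not welch)
    n1, n2 = len(aa), len(bb)
    if welch:
        df = float(res.df)
        se = float(np.sqrt(np.var(aa, ddof=1) / n1 + np.var(bb, ddof=1) / n2))
    else:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * np.var(aa, ddof=1) + (n2 - 1) * np.var(bb, ddof=1)) / df
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    return TTestResult("two_sample", float(res.statistic), df, float(res.pvalue),
                       float(np.mean(aa) - np.mean(bb)), se)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pairwise_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult | None:
    """Pearson r over pairwise-complete observations; None if n < 3."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    n = int(ok.sum())
    if n < 3:
        return None
    res = sps.pearsonr(xa[ok], ya[ok])
    return CorrelationResult(float(res.statistic), n, float(res.pvalue))


def correlation_matrix(
    table: pd.DataFrame, variables: Sequence[str]
) -> dict[tuple[str, str], CorrelationResult | None]:
    """Pairwise-complete Pearson correlations for every variable pair.

    Mirrors a zero-order correlation table where each cell has its own n.
    Diagonal cells are r = 1 with the variable's complete-case n. Cells with
    fewer than 3 complete pairs are None (not computable).
    """
    out: dict[tuple[str, str], CorrelationResult | None] = {}
    for v in variables:
        n = int(np.isfinite(table[v].to_numpy(float)).sum())
        out[(v, v)] = CorrelationResult(1.0, n, 0.0) if n >= 3 else None
    for a, b in combinations(variables, 2):
        cell = pairwise_correlation(table[a].to_numpy(float), table[b].to_numpy(float))
        out[(a, b)] = cell
        out[(b, a)] = cell
    return out


def correlation_table(
    matrix: Mapping[tuple[str, str], CorrelationResult | None], variables: Sequence[str]
) -> pd.DataFrame:
    """Long-format (pair, r, n, p) frame for the upper triangle."""
    rows = []
    for a, b in combinations(variables, 2):
        cell = matrix[(a, b)]
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": cell.r if cell else np.nan,
                "n": cell.n if cell else 0,
                "p": cell.p if cell else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortClassification:
    n_predictive: int
    n_reactive: int
    n_excluded: int
    pct_predictive: float
    pct_reactive: float
    pct_excluded: float
    pct_predictive_of_included: float | None


def classify_cohort(scores: Iterable) -> CohortClassification:
    """Counts and percentages of predictive / reactive / excluded participants.

    ``scores`` is any iterable of objects with a ``classification`` attribute.
    Percentages of the total cohort always sum to 100 (empty cohort reports
    zeros); the predictive share of included participants is None when nobody
    is included.
    """
    counts = {"predictive": 0, "reactive": 0, "excluded": 0}
    for s in scores:
        counts[s.classification] += 1
    total = sum(counts.values())
    included = counts["predictive"] + counts["reactive"]

    def pct(k: int) -> float:
        return 100.0 * k / total if total else 0.0

    return CohortClassification(
        counts["predictive"], counts["reactive"], counts["excluded"],
        pct(counts["predictive"]), pct(counts["reactive"]), pct(counts["excluded"]),
        100.0 * counts["predictive"] / included if included else None,
    )


def skewness(values: Sequence[float]) -> float:
    """Adjusted Fisher–Pearson standardized third moment (sample skewness)."""
    a = _finite(values)
    if len(a) < 3:
        raise ValidationError("skewness requires n >= 3")
    if np.std(a, ddof=1) == 0.0:
        raise ValidationError("skewness undefined for zero-variance data")
    return float(sps.skew(a, bias=False))
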