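"""Evaluation statistics for cross-laboratory comparisons.

Coefficient of variation (CV = SD/mean x 100, sample SD), the asymptotic
CV-equality test of Feltz & Miller (as implemented in the R package
``cvequality``), paired t-test, Pearson correlation / R-squared (with an
optional log10 pre-transform), and limit-of-detection reporting over
spike-in dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: sample SD (n-1) / mean x 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cv needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("cv undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


class CVEqualityResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def cv_equality_test(groups: Sequence[Sequence[float]]) -> CVEqualityResult:
    """Asymptotic test of equal coefficients of variation across k groups
    (Feltz & Miller 1996).

    With m_i = n_i - 1, c_i the group CVs (as fractions) and the pooled
    CV c = sum(m_i c_i) / sum(m_i), the statistic

        D = sum_i m_i (c_i - c)^2 / (c^2 (0.5 + c^2))

    is asymptotically chi-square with k - 1 degrees of freedom under the
    null of equal CVs.
    """
    if len(groups) < 2:
        raise ValueError("cv_equality_test needs at least 2 groups")
    m, c = [], []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError("each group needs at least 2 values")
        mean = arr.mean()
        if mean == 0:
            raise ZeroDivisionError("group mean of zero: CV undefined")
        m.append(arr.size - 1)
        c.append(arr.std(ddof=1) / mean)
    m_arr = np.asarray(m, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    pooled = float((m_arr * c_arr).sum() / m_arr.sum())
    if pooled == 0:
        # all groups have zero dispersion: trivially equal CVs
        return CVEqualityResult(0.0, len(groups) - 1, 1.0)
    d_stat = float((m_arr * (c_arr - pooled) ** 2).sum()
                   / (pooled**2 * (0.5 + pooled**2)))
    df = len(groups) - 1
    p = float(sps.chi2.sf(d_stat, df))
    return CVEqualityResult(d_stat, df, p)


class PairedTResult(NamedTuple):
    statistic: float
    pvalue: float


def paired_t(x: Sequence[float], y: Sequence[float],
             log10_transform: bool = False) -> PairedTResult:
    """Two-sided paired t-test on matched observations."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError("paired_t: length mismatch")
    if x_arr.size < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    if log10_transform:
        x_arr, y_arr = np.log10(x_arr), np.log10(y_arr)
    res = sps.ttest_rel(x_arr, y_arr)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # all differences zero
        t, p = 0.0, 1.0
    return PairedTResult(t, p)


class PearsonResult(NamedTuple):
    r: float
    r2: float
    pvalue: float


def pearson_r2(x: Sequence[float], y: Sequence[float],
               log10_transform: bool = False) -> PearsonResult:
    """Pearson correlation with R^2 and two-sided p; optionally on
    log10-transformed data (frequencies spanning decades are closer to
    normal on the log scale)."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size or x_arr.size < 3:
        raise ValueError("pearson_r2 needs two equal-length vectors, n >= 3")
    if log10_transform:
        x_arr, y_arr = np.log10(x_arr), np.log10(y_arr)
    if x_arr.std() == 0 or y_arr.std() == 0:
        raise ValueError("pearson_r2: zero variance")
    res = sps.pearsonr(x_arr, y_arr)
    r = float(res.statistic)
    return PearsonResult(r, r * r, float(res.pvalue))


# ----------------------------------------------------------------------
# Limit of detection
# ----------------------------------------------------------------------

#: Conventional detection threshold frequency: 10 events out of 10^6 live
#: single lymphocytes.
THRESHOLD_LINE_PCT = 0.001


@dataclass
class LoDReport:
    """Limit-of-detection summary over a dilution series."""

    table: pd.DataFrame  # step, theoretical_pct, duplicate, estimated_pct, detected
    lowest_detected_pct: float | None  # smallest theoretical % detected in all dups
    threshold_line_pct: float = THRESHOLD_LINE_PCT


def lod_report(
    series: Sequence[tuple[float, Sequence[float], Sequence[bool]]]
) -> LoDReport:
    """Tabulate a dilution series and find the limit of detection.

    `series` holds, per dilution step, (theoretical %, estimated % per
    duplicate, detected flag per duplicate).  Steps are reported in
    decreasing theoretical order; the limit of detection is the smallest
    theoretical frequency detected in every duplicate.
    """
    if not series:
        raise ValueError("lod_report: empty series")
    ordered = sorted(series, key=lambda s: -s[0])
    rows = []
    lowest: float | None = None
    for step, (theo, estimates, flags) in enumerate(ordered, start=1):
        estimates = list(estimates)
        flags = list(flags)
        if len(estimates) != len(flags):
            raise ValueError("estimates and detection flags differ in length")
        for dup, (est, det) in enumerate(zip(estimates, flags)):
            rows.append(dict(step=step, theoretical_pct=theo, duplicate=dup,
                             estimated_pct=est, detected=bool(det)))
        if theo > 0 and flags and all(flags):
            if lowest is None or theo < lowest:
                lowest = theo
    table = pd.DataFrame(rows, columns=["step", "theoretical_pct", "duplicate",
                                        "estimated_pct", "detected"])
    return LoDReport(table=table, lowest_detected_pct=lowest)
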