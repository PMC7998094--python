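"""Two-group comparison battery for mucosal measurement tables.

The statistical surface of the pipeline: median/IQR summaries,
Mann–Whitney U for non-normal measurements, a Shapiro–Wilk-gated pooled
t-test for measurements that pass normality (after log10 transform for
cytokine concentrations), Fisher's exact test for categorical tables and
above-detection-limit counts, OLS slope checks against age, and the
luteal-phase progesterone rule.

No multiple-testing correction is applied; every result carries its test
name, per-group n, medians and IQRs so tables can be reported directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "ComparisonResult",
    "median_iqr",
    "mann_whitney",
    "unpaired_t",
    "normality_gate",
    "compare_gated",
    "fisher_exact",
    "summarize_categorical",
    "detection_limit_comparison",
    "univariate_age_check",
    "luteal_flag",
    "log10_transform",
]

logger = logging.getLogger(__name__)

#: progesterone (ng/mL) above which a sample is staged as luteal phase
LUTEAL_PROGESTERONE_NG_ML = 1.2

#: minimum group size for hypothesis tests
MIN_N_TEST = 3


@dataclass
class GroupedMeasurements:
    """A measurement vector with two-group labels and optional extras."""

    values: np.ndarray
    groups: np.ndarray
    above_limit: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must have the same length")
        labels = set(np.unique(self.groups))
        if not labels.issubset({"A", "B"}):
            raise ValueError(f"group labels must be 'A'/'B', got {sorted(labels)}")
        if self.above_limit is not None:
            self.above_limit = np.asarray(self.above_limit, dtype=bool)

    def group(self, label: str) -> np.ndarray:
        return self.values[self.groups == label]

    def flags(self, label: str) -> np.ndarray:
        if self.above_limit is None:
            raise ValueError("no detection-limit flags present")
        return self.above_limit[self.groups == label]


@dataclass
class ComparisonResult:
    """One two-group comparison with its descriptive summaries."""

    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float = float("nan")
    iqr_a: tuple[float, float] = (float("nan"), float("nan"))
    median_b: float = float("nan")
    iqr_b: tuple[float, float] = (float("nan"), float("nan"))
    method_detail: str = ""

    def to_row(self) -> dict:
        return dict(
            test_name=self.test_name,
            statistic=self.statistic,
            p_value=self.p_value,
            n_a=self.n_a,
            n_b=self.n_b,
            median_a=self.median_a,
            q1_a=self.iqr_a[0],
            q3_a=self.iqr_a[1],
            median_b=self.median_b,
            q1_b=self.iqr_b[0],
            q3_b=self.iqr_b[1],
            method_detail=self.method_detail,
        )


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation between order statistics)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr of empty data")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    med, q1, q3 = np.percentile(v, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def _describe(a: np.ndarray, b: np.ndarray) -> dict:
    ma, q1a, q3a = median_iqr(a)
    mb, q1b, q3b = median_iqr(b)
    return dict(
        n_a=len(a), n_b=len(b),
        median_a=ma, iqr_a=(q1a, q3a),
        median_b=mb, iqr_b=(q1b, q3b),
    )


def _check_test_sizes(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) < MIN_N_TEST or len(b) < MIN_N_TEST:
        raise ValueError(
            f"test refused: need at least {MIN_N_TEST} observations per group "
            f"(got {len(a)} and {len(b)})"
        )


#: pooled-sample-size limit below which the exact Mann–Whitney null is used
_EXACT_MW_LIMIT = 12


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    For pooled n <= 12 with no ties the exact permutation null is used;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical groups give p = 1 exactly).  The method
    actually used is recorded in ``method_detail``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_test_sizes(a, b)
    desc = _describe(a, b)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.warning("all values identical across both groups; p = 1")
        return ComparisonResult(
            test_name="mann_whitney",
            statistic=len(a) * len(b) / 2.0,
            p_value=1.0,
            method_detail="degenerate (all values identical)",
            **desc,
        )

    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return ComparisonResult(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method_detail=method + (" (tie-corrected)" if method == "asymptotic" and has_ties else ""),
        **desc,
    )


def unpaired_t(a, b) -> ComparisonResult:
    """Two-sided unpaired t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_test_sizes(a, b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    desc = _describe(a, b)
    res = sps.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        test_name="unpaired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method_detail="pooled variance",
        **desc,
    )


def normality_gate(values, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk normality check; True when the sample passes (p >= alpha)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.ptp(v) == 0:
        return False
    _, p = sps.shapiro(v)
    return bool(p >= alpha)


def compare_gated(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated comparison: pooled t-test if both groups pass
    Shapiro–Wilk at ``alpha``, otherwise Mann–Whitney U.  The routing
    decision is recorded in ``method_detail``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_test_sizes(a, b)
    normal = normality_gate(a, alpha) and normality_gate(b, alpha)
    if normal:
        res = unpaired_t(a, b)
        res.method_detail = "normality gate passed -> t-test; " + res.method_detail
    else:
        res = mann_whitney(a, b)
        res.method_detail = "normality gate failed -> Mann-Whitney; " + res.method_detail
    return res


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample
    (cross-product) estimate.  A zero row or column margin makes the
    table uninformative: p = 1 and the odds ratio is NaN.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.rint(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.rint(t).astype(int)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def summarize_categorical(counts) -> pd.DataFrame:
    """Category percentages out of the column total.

    ``counts`` maps category -> non-negative integer count.  Returns a
    DataFrame with the raw count, exact percentage and the integer
    percentage used for display.
    """
    s = pd.Series(counts, dtype=float)
    if s.empty or (s < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(s, np.rint(s)):
        raise ValueError("counts must be integers")
    total = s.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    pct = 100.0 * s / total
    return pd.DataFrame(
        {"count": s.astype(int), "pct": pct, "pct_rounded": pct.round(0).astype(int)}
    )


def detection_limit_comparison(flags_a, flags_b) -> ComparisonResult:
    """Compare the number of above-detection-limit samples between groups.

    Builds the 2x2 table of above/below x group and applies Fisher's
    exact test; the statistic is the sample odds ratio.
    """
    fa = np.asarray(flags_a, dtype=bool)
    fb = np.asarray(flags_b, dtype=bool)
    table = [
        [int(fa.sum()), int((~fa).sum())],
        [int(fb.sum()), int((~fb).sum())],
    ]
    odds, p = fisher_exact(table)
    return ComparisonResult(
        test_name="fisher_exact_detection_limit",
        statistic=odds,
        p_value=p,
        n_a=len(fa),
        n_b=len(fb),
        method_detail=f"above-limit counts A={table[0][0]}/{len(fa)}, B={table[1][0]}/{len(fb)}",
    )


def univariate_age_check(values, age) -> tuple[float, float]:
    """OLS slope of a measurement on age and the two-sided p for slope = 0."""
    v = np.asarray(values, dtype=float)
    x = np.asarray(age, dtype=float)
    if v.shape != x.shape:
        raise ValueError("values and age must have equal length")
    if len(v) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("age is constant; regression undefined")
    res = sps.linregress(x, v)
    return float(res.slope), float(res.pvalue)


def luteal_flag(progesterone_ng_ml):
    """True when plasma progesterone exceeds 1.2 ng/mL (luteal phase).

    The inequality is strict: a value of exactly 1.2 is not luteal.
    Accepts scalars or arrays.
    """
    p = np.asarray(progesterone_ng_ml, dtype=float)
    if np.any(p < 0):
        raise ValueError("progesterone concentration cannot be negative")
    out = p > LUTEAL_PROGESTERONE_NG_ML
    return bool(out) if out.ndim == 0 else out


def log10_transform(values) -> np.ndarray:
    """log10 of strictly positive concentrations (cytokine convention)."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("log10 transform requires strictly positive values")
    return np.log10(v)
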