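"""Cohort-level statistics: Welch range screen for tumor-vs-cell-line
expression, correlation screening with Benjamini-Hochberg FDR control,
top-quartile/median concordance, Kaplan-Meier / log-rank survival
comparison, and qPCR ddCt fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import ExpressionMatrix, SurvivalRecord

__all__ = [
    "TestResult",
    "CorrelationResult",
    "KMCurve",
    "QpcrMeasurement",
    "welch_t",
    "range_screen",
    "bh_fdr",
    "correlation_screen",
    "quartile_concordance",
    "km_logrank",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class TestResult:
    """A two-sample test outcome with Welch-Satterthwaite df."""

    statistic: float
    df: float
    p: float
    direction: int  # sign of mean(A) - mean(B)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Unpaired two-sided t-test with Welch's correction.

    Degenerate case: both groups constant with equal means returns
    ``t = 0, p = 1`` by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least two values per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t requires finite values")
    diff = float(a.mean() - b.mean())
    direction = int(np.sign(diff))
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if diff == 0.0:
            return TestResult(statistic=0.0, df=float(a.size + b.size - 2), p=1.0,
                              direction=0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        direction=direction,
    )


def range_screen(
    tumors: ExpressionMatrix,
    celllines: ExpressionMatrix,
    genes: Iterable[str],
    p_cut: float = 0.01,
) -> tuple[set[str], list[str]]:
    """Screen for genes expressed higher in tumors than in cell lines.

    A gene passes when the tumor mean exceeds the cell-line mean and the
    two-sided Welch p-value is below ``p_cut``. Returns the passing set
    and the list of genes skipped because they were missing from either
    matrix.
    """
    passed: set[str] = set()
    skipped: list[str] = []
    for gene in genes:
        if gene not in tumors or gene not in celllines:
            skipped.append(gene)
            continue
        result = welch_t(tumors.values_for(gene), celllines.values_for(gene))
        if result.direction > 0 and result.p < p_cut:
            passed.add(gene)
    return passed, skipped


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class CorrelationResult:
    """Per-candidate correlation with the regulator, with BH-adjusted q."""

    gene_id: str
    r: float
    p: float
    q: float
    defined: bool
    passed: bool


def correlation_screen(
    matrix: ExpressionMatrix,
    regulator: str,
    candidates: Iterable[str],
    method: str = "pearson",
    q_cut: float = 0.01,
    log_transform: bool = True,
) -> list[CorrelationResult]:
    """Correlate each candidate gene with the regulator across samples.

    Pearson correlations are computed on ``log2(x + 1)``-transformed
    values (disable with ``log_transform=False``); Spearman on ranks of
    the raw values. q-values are BH-adjusted over the candidate set, and
    a candidate passes at ``q < q_cut``. Zero-variance candidates are
    flagged undefined and never pass.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if regulator not in matrix:
        raise KeyError(f"regulator {regulator!r} not in matrix")
    if matrix.n_samples < 3:
        raise ValueError("correlation_screen requires >= 3 samples")

    def transform(x: np.ndarray) -> np.ndarray:
        return np.log2(x + 1.0) if (log_transform and method == "pearson") else x

    reg = transform(matrix.values_for(regulator))
    names: list[str] = []
    rs: list[float] = []
    ps: list[float] = []
    defined: list[bool] = []
    for gene in candidates:
        names.append(gene)
        x = transform(matrix.values_for(gene))
        if np.std(x) == 0.0 or np.std(reg) == 0.0:
            rs.append(float("nan"))
            ps.append(1.0)
            defined.append(False)
            continue
        if method == "pearson":
            r, p = stats.pearsonr(reg, x)
        else:
            r, p = stats.spearmanr(reg, x)
        rs.append(float(r))
        ps.append(float(p))
        defined.append(True)
    qs = bh_fdr(ps)
    return [
        CorrelationResult(
            gene_id=g,
            r=r,
            p=p,
            q=q,
            defined=ok,
            passed=bool(ok and q < q_cut),
        )
        for g, r, p, q, ok in zip(names, rs, ps, qs, defined)
    ]


def quartile_concordance(
    matrix: ExpressionMatrix, regulator: str, target: str
) -> tuple[int, int]:
    """Top-quartile regulator samples expressing >= median target levels.

    ``n = ceil(N / 4)`` samples with the highest regulator expression
    (ties broken by sample order); ``k`` counts those whose target
    expression is at or above the cohort-wide median of the target.
    """
    n_samples = matrix.n_samples
    if n_samples < 4:
        raise ValueError("quartile_concordance requires >= 4 samples")
    reg = matrix.values_for(regulator)
    tgt = matrix.values_for(target)
    n = math.ceil(n_samples / 4)
    # stable sort on descending expression: earlier samples win ties
    top_idx = np.argsort(-reg, kind="stable")[:n]
    median = float(np.median(tgt))
    k = int(np.sum(tgt[top_idx] >= median))
    return k, n


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier product-limit curve (step values at event times)."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        surv = np.asarray(self.survival)
        if surv.size and (np.diff(surv) > 1e-12).any():
            raise ValueError("survival probabilities must be non-increasing")


def _km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=tuple(float(t) for t in sf.index),
        survival=tuple(float(v) for v in sf.to_numpy()),
        at_risk=tuple(int(v) for v in table["at_risk"].to_numpy()),
    )


def km_logrank(
    records: Sequence[SurvivalRecord], split: str | float = "median"
) -> tuple[KMCurve, KMCurve, float, float]:
    """Median (or fixed-value) expression split with a two-group log-rank test.

    Returns (high curve, low curve, chi-square, p). The high group is
    ``expression > cutoff``. With no events anywhere both curves are flat
    at 1 and ``chi2 = 0, p = 1``.
    """
    if not records:
        raise ValueError("km_logrank requires records")
    expr = np.array([r.expression for r in records], dtype=float)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    cutoff = float(np.median(expr)) if split == "median" else float(split)
    high = expr > cutoff
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError(
            f"split at {cutoff} leaves a group with fewer than two records"
        )
    curve_high = _km_curve(times[high], events[high])
    curve_low = _km_curve(times[~high], events[~high])
    if events.sum() == 0:
        return curve_high, curve_low, 0.0, 1.0
    from lifelines.statistics import logrank_test

    res = logrank_test(times[high], times[~high], events[high], events[~high])
    return curve_high, curve_low, float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired target/reference Ct values from one condition."""

    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression ``2 ** -(dCt_treated - dCt_control)``."""
    return 2.0 ** -(treated.dct - control.dct)
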