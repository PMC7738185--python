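"""Normality-gated two-sample test dispatcher and correlation selector.

Every cross-group comparison in the pipeline goes through
:func:`dispatch_compare`, which mirrors the classical decision tree used in
experimental tissue-biomechanics studies: Shapiro–Wilk normality on each
sample, an F-test of variance homogeneity when both pass, then Student's t,
Welch's t, or the Wilcoxon rank-sum test as appropriate.  Correlations are
dispatched to Pearson or Spearman by the same normality gate plus an ordinal
flag (e.g. regurgitation severity grades 0, 0.5, 1, 2, 3, 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "dispatch_compare",
    "dispatch_correlate",
    "type_error_calibration",
]

#: Shapiro–Wilk and F-test gate level used to choose the test (configurable).
DEFAULT_GATE_ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one gated two-sample comparison."""

    chosen_test: str  # "student_t" | "welch_t" | "wilcoxon_rank_sum"
    p_value: float
    statistic: float
    normality_p: tuple[float, float]  # Shapiro–Wilk p per sample (nan if undefined)
    variance_test_p: float  # two-sided F-test p (nan when not reached)
    central_summary_kind: tuple[str, str]  # "mean" | "median" per sample
    central_summary: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    normality_p: tuple[float, float]


def _shapiro_p(x: np.ndarray) -> tuple[float, str | None]:
    """Shapiro–Wilk p-value, with a flag when normality is undefined."""
    if x.size < 3:
        return np.nan, "too_few_for_normality"
    if np.ptp(x) == 0:
        return np.nan, "constant_sample"
    return float(sps.shapiro(x).pvalue), None


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test of equal variances (variance-ratio test)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        return np.nan
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p_one = sps.f.sf(f, dfa, dfb) if f >= 1 else sps.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * p_one))


def _rank_sum(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) p-value.

    Exact null distribution for pooled n <= 20 without ties; otherwise the
    normal approximation with tie and continuity correction.
    """
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def dispatch_compare(
    sample_a,
    sample_b,
    tails: str = "two",
    alpha: float = 0.05,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
) -> ComparisonResult:
    """Run the normality-gated two-sample comparison.

    Decision tree: Shapiro–Wilk on each sample.  If both pass
    (p >= ``gate_alpha``), an F-test compares variances: similar variances
    give Student's t, dissimilar give Welch's t.  If either sample fails
    normality (or normality is undefined, e.g. a constant sample), the
    Wilcoxon rank-sum test is used.  Each sample is summarized by its mean
    if it passed normality and by its median otherwise.

    Parameters
    ----------
    tails:
        "two" (default), "less", or "greater" (alternative for sample_a
        relative to sample_b).  One-sided use must be declared explicitly.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[tails]

    flags: list[str] = []
    pa, fa = _shapiro_p(a)
    pb, fb = _shapiro_p(b)
    for f in (fa, fb):
        if f:
            flags.append(f)
    a_normal = bool(pa >= gate_alpha) if np.isfinite(pa) else False
    b_normal = bool(pb >= gate_alpha) if np.isfinite(pb) else False

    var_p = np.nan
    if a_normal and b_normal:
        var_p = _f_test_p(a, b)
        equal_var = bool(var_p >= gate_alpha) if np.isfinite(var_p) else False
        chosen = "student_t" if equal_var else "welch_t"
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        chosen = "wilcoxon_rank_sum"
        stat, p = _rank_sum(a, b, alternative)

    kinds = ("mean" if a_normal else "median", "mean" if b_normal else "median")
    centrals = (
        float(np.mean(a)) if a_normal else float(np.median(a)),
        float(np.mean(b)) if b_normal else float(np.median(b)),
    )
    return ComparisonResult(
        chosen_test=chosen,
        p_value=p,
        statistic=stat,
        normality_p=(pa, pb),
        variance_test_p=var_p,
        central_summary_kind=kinds,
        central_summary=centrals,
        flags=flags,
    )


def dispatch_correlate(
    x,
    y,
    x_ordinal: bool = False,
    y_ordinal: bool = False,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
) -> CorrelationResult:
    """Pearson or Spearman correlation, chosen by ordinality and normality.

    Spearman rank correlation is used when either variable is declared
    ordinal or fails the Shapiro–Wilk normality gate; otherwise Pearson.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    px, _ = _shapiro_p(xv)
    py, _ = _shapiro_p(yv)
    nonnormal = (not np.isfinite(px)) or (not np.isfinite(py)) or px < gate_alpha or py < gate_alpha
    if x_ordinal or y_ordinal or nonnormal:
        res = sps.spearmanr(xv, yv)
        method = "spearman"
    else:
        res = sps.pearsonr(xv, yv)
        method = "pearson"
    return CorrelationResult(
        method=method,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(px, py),
    )


def type_error_calibration(
    n_a: int = 15,
    n_b: int = 15,
    n_reps: int = 2000,
    alpha: float = 0.05,
    effect_sd: float = 0.0,
    seed: int = 0,
    tails: str = "two",
) -> float:
    """Empirical rejection rate of the dispatcher under a normal simulation.

    ``effect_sd`` is the true mean shift of group b in units of the common
    standard deviation; 0 gives the type-I error rate, > 0 gives power.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n_a)
        b = rng.standard_normal(n_b) + effect_sd
        res = dispatch_compare(a, b, tails=tails, alpha=alpha)
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_reps
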