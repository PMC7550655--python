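"""Study-level statistics: normality screening, one-way ANOVA (raw and
from summary cells), Student–Newman–Keuls post hoc, Pearson correlation.

``anova_from_summary`` exists because published tables report only
mean ± SD and n per cell: the classical between/within decomposition is
algebraically a function of those summaries alone, so the printed F
statistics can be recomputed without the raw animal data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .acquisition import ValidationError
from .tumor import SummaryCell

__all__ = ["AnovaResult", "PairComparison", "PosthocResult",
           "CorrelationResult", "NormalityResult", "ks_normality",
           "anova_oneway", "anova_from_summary", "snk_posthoc", "pearson"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_between: float
    ms_within: float
    degenerate: bool = False  # zero within-variance with unequal means


class NormalityResult(NamedTuple):
    statistic: float
    p: float
    degenerate: bool


@dataclass(frozen=True)
class PairComparison:
    """One SNK pairwise comparison between rank-ordered group means."""

    group_low: object
    group_high: object
    q: float
    critical: float
    r: int          # number of means spanned
    reject: bool
    tested: bool    # False when blocked by an enclosing non-rejection


@dataclass(frozen=True)
class PosthocResult:
    comparisons: tuple[PairComparison, ...]
    alpha: float

    @property
    def rejected(self) -> tuple[tuple[object, object], ...]:
        return tuple((c.group_low, c.group_high)
                     for c in self.comparisons if c.reject)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    strength: str   # 'high' (|r| > 0.8), 'moderate' (0.5–0.8), else 'weak'


def ks_normality(sample: Sequence[float]) -> NormalityResult:
    """Kolmogorov–Smirnov normality screen with estimated parameters.

    Mean and SD are taken from the sample, so the Lilliefors correction
    of the p-value is used (testing against a fully specified normal
    would be anti-conservative).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValidationError("sample: need at least 3 observations")
    if np.ptp(x) == 0:
        return NormalityResult(float("nan"), float("nan"), True)
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), False)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on raw samples."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("groups: need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValidationError("groups: every group needs n >= 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, ms_b, 0.0,
                           degenerate=True)
    F = ms_b / ms_w
    return AnovaResult(float(F), df_b, df_w,
                       float(sps.f.sf(F, df_b, df_w)), ms_b, ms_w)


def anova_from_summary(cells: Sequence[SummaryCell]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group mean ± SD and n.

    SS_between = Σ nᵢ(mᵢ − m̄)² with m̄ the n-weighted grand mean;
    MS_within pools the cell variances with nᵢ−1 weights. Agrees exactly
    with :func:`anova_oneway` when the cells are computed from raw
    samples.
    """
    if len(cells) < 2:
        raise ValidationError("cells: need at least 2 cells")
    ns = np.array([c.n for c in cells], dtype=float)
    means = np.array([c.mean for c in cells])
    sds = np.array([c.sd for c in cells])
    grand = float(np.sum(ns * means) / ns.sum())
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    df_b = len(cells) - 1
    df_w = int(ns.sum()) - len(cells)
    ms_b = ss_b / df_b
    ms_w = float(np.sum((ns - 1) * sds ** 2) / np.sum(ns - 1))
    if ms_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, ms_b, 0.0,
                           degenerate=True)
    F = ms_b / ms_w
    return AnovaResult(float(F), df_b, df_w,
                       float(sps.f.sf(F, df_b, df_w)), ms_b, ms_w)


@lru_cache(maxsize=4096)
def _q_critical(alpha: float, r: int, df: int) -> float:
    """Upper studentized-range quantile (cached: ppf is expensive)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, r, df))


def snk_posthoc(groups: Sequence[Sequence[float]],
                labels: Sequence[object] | None = None,
                alpha: float = 0.05) -> PosthocResult:
    """Student–Newman–Keuls stepwise post hoc comparisons.

    Group means are rank-ordered; a pair spanning r means is compared
    with the studentized-range critical value q(alpha, r, df_within).
    Comparisons proceed from the widest span inward and a pair enclosed
    by a non-rejected span is not tested (standard SNK protection).
    Unequal group sizes use the harmonic-mean standard error. Ties in
    means keep stable (input) order.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(gs)))
    anova = anova_oneway(gs)
    means = np.array([g.mean() for g in gs])
    order = np.argsort(means, kind="stable")
    k = len(gs)
    ms_w, df_w = anova.ms_within, anova.df_within
    blocked: list[tuple[int, int]] = []  # non-rejected spans (rank idx)
    comps: list[PairComparison] = []
    for r in range(k, 1, -1):
        for lo in range(0, k - r + 1):
            hi = lo + r - 1
            gi, gj = order[lo], order[hi]
            inside = any(b_lo <= lo and hi <= b_hi for b_lo, b_hi in blocked)
            crit = _q_critical(alpha, r, df_w)
            se = np.sqrt(ms_w / 2.0 * (1.0 / gs[gi].size
                                       + 1.0 / gs[gj].size))
            q = float((means[gj] - means[gi]) / se) if se > 0 else \
                (0.0 if means[gj] == means[gi] else float("inf"))
            if inside:
                comps.append(PairComparison(labels[gi], labels[gj], q, crit,
                                            r, False, False))
                continue
            reject = q > crit
            if not reject:
                blocked.append((lo, hi))
            comps.append(PairComparison(labels[gi], labels[gj], q, crit,
                                        r, reject, True))
    return PosthocResult(tuple(comps), alpha)


_STRENGTH_HIGH = 0.8
_STRENGTH_MODERATE = 0.5


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a strength label.

    p is two-sided via the t transform with n−2 df. |r| above 0.8 is
    labeled 'high', between 0.5 and 0.8 'moderate', below 0.5 'weak'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x/y: unequal lengths")
    if x.size < 3:
        raise ValidationError("x/y: need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("x/y: constant input, correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) > _STRENGTH_HIGH:
        strength = "high"
    elif abs(r) >= _STRENGTH_MODERATE:
        strength = "moderate"
    else:
        strength = "weak"
    return CorrelationResult(r, float(res.pvalue), int(x.size), strength)
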