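"""Group-comparison statistics: Student's t, BCa bootstrap estimation
statistics (mean difference with 95% CI), Holm-Sidak step-down adjustment,
and balanced mixed-design (split-plot) two-way ANOVA.

The estimation-statistics layer reports effect sizes as the mean difference
MD = mean(B) - mean(A) with a bias-corrected-and-accelerated (BCa) bootstrap
confidence interval, resampling within groups; the point estimate itself is
never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError

__all__ = [
    "GroupComparison",
    "student_t",
    "bootstrap_md_ci",
    "holm_sidak",
    "mixed_anova",
    "MixedAnovaResult",
]


@dataclass(frozen=True)
class GroupComparison:
    """Mean difference (B - A) with bootstrap CI and the pooled t-test."""

    md: float
    ci95: Tuple[float, float]
    t: float
    p: float
    n_a: int
    n_b: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.md <= hi + 1e-12):
            raise ValueError("CI must bracket the point estimate")


def student_t(a, b, two_tailed: bool = True) -> Tuple[float, float]:
    """Pooled-variance two-sample Student's t test, df = n_a + n_b - 2.

    Zero pooled variance with equal means returns (0, 1); with unequal means
    the statistic is infinite (p = 0) and a warning is emitted.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; t is infinite")
        return float(np.copysign(np.inf, a.mean() - b.mean())), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not two_tailed:
        p = p / 2.0
    return float(t), float(p)


def _bca_interval(boots: np.ndarray, theta_hat: float, jack: np.ndarray,
                  alpha: float = 0.05) -> Tuple[float, float]:
    """BCa interval from a bootstrap distribution and jackknife replicates."""
    b = boots.size
    # bias correction; midrank treatment of ties at theta_hat
    prop = (np.sum(boots < theta_hat) + 0.5 * np.sum(boots == theta_hat)) / b
    prop = min(max(prop, 0.5 / b), 1.0 - 0.5 / b)
    z0 = sps.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a_hat = num / den if den > 0 else 0.0
    z = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = sps.norm.cdf(z0 + (z0 + z) / (1.0 - a_hat * (z0 + z)))
    lo, hi = np.quantile(boots, adj)
    return float(lo), float(hi)


def bootstrap_md_ci(a, b, n_boot: int = 5000, seed=None,
                    alpha: float = 0.05) -> GroupComparison:
    """Mean difference mean(b) - mean(a) with a BCa bootstrap 95% CI.

    Groups are resampled independently (within-group resampling); the
    acceleration constant comes from a leave-one-out jackknife over both
    groups. Fully seeded and reproducible. Degenerate input (both groups
    constant) collapses the CI to the point estimate and sets the
    ``degenerate`` flag.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    md = float(b.mean() - a.mean())
    t, p = student_t(a, b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return GroupComparison(md, (md, md), t, p, a.size, b.size, degenerate=True)
    boots = (b[rng.integers(0, b.size, (n_boot, b.size))].mean(axis=1)
             - a[rng.integers(0, a.size, (n_boot, a.size))].mean(axis=1))
    # jackknife of the MD: leaving out one obs of a, then one of b
    jack_a = (np.sum(a) - a) / (a.size - 1)
    jack_b = (np.sum(b) - b) / (b.size - 1)
    jack = np.concatenate([b.mean() - jack_a, jack_b - a.mean()])
    lo, hi = _bca_interval(boots, md, jack, alpha)
    degenerate = bool(np.ptp(boots) == 0)
    lo, hi = min(lo, md), max(hi, md)
    return GroupComparison(md, (lo, hi), t, p, a.size, b.size, degenerate=degenerate)


def holm_sidak(pvals: Sequence[float], alpha: float = 0.05
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down multiple-comparison adjustment.

    Sorting the m raw p-values ascending, the i-th (1-based) adjusted value
    is 1 - (1 - p_(i))^(m - i + 1), enforced monotone non-decreasing;
    hypotheses are rejected while the adjusted value stays below ``alpha``.
    Returns (adjusted p-values, reject flags) in the original order.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ParameterError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(adj_sorted)
    adj[order] = np.minimum(adj_sorted, 1.0)
    reject = adj < alpha
    return adj, reject


@dataclass(frozen=True)
class MixedAnovaResult:
    """Split-plot ANOVA: between-subjects factor x within-subjects factor."""

    f_between: float
    p_between: float
    f_within: float
    p_within: float
    f_interaction: float
    p_interaction: float
    df: dict
    ss: dict


def mixed_anova(data: np.ndarray, groups: Sequence) -> MixedAnovaResult:
    """Classical balanced mixed-design (split-plot) two-way ANOVA.

    Parameters
    ----------
    data : (n_subjects, n_levels) array
        One row per subject, one column per within-subject level. Every
        subject must have every level (no missing cells).
    groups : sequence of length n_subjects
        Between-subjects group label of each row.

    The between-subjects factor is tested against the subject-within-group
    error; the within factor and the interaction against the
    subject x within residual.
    """
    y = np.asarray(data, float)
    if y.ndim != 2:
        raise ParameterError("data must be 2-D (subjects x within levels)")
    if not np.all(np.isfinite(y)):
        raise ParameterError("missing cells are not supported")
    groups = np.asarray(groups)
    if groups.size != y.shape[0]:
        raise ParameterError("one group label per subject is required")
    labels, ginv = np.unique(groups, return_inverse=True)
    g = labels.size
    n_subj, k = y.shape
    counts = np.bincount(ginv)
    if g < 2 or np.any(counts < 2):
        raise ParameterError("need >= 2 groups with >= 2 subjects each")

    gm = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[ginv == i].mean() for i in range(g)])
    level_means = y.mean(axis=0)
    cell_means = np.array([y[ginv == i].mean(axis=0) for i in range(g)])

    ss_total = np.sum((y - gm) ** 2)
    ss_between_subj = k * np.sum((subj_means - gm) ** 2)
    ss_group = k * np.sum(counts * (group_means - gm) ** 2)
    ss_subj_err = ss_between_subj - ss_group
    ss_within_lvl = n_subj * np.sum((level_means - gm) ** 2)
    ss_inter = np.sum(counts[:, None] * (cell_means - group_means[:, None]
                                         - level_means[None, :] + gm) ** 2)
    ss_err = ss_total - ss_group - ss_subj_err - ss_within_lvl - ss_inter

    df_group = g - 1
    df_subj_err = n_subj - g
    df_within = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (n_subj - g) * (k - 1)

    def f_and_p(ss_eff, df_eff, ss_e, df_e):
        ms_e = ss_e / df_e if df_e > 0 else np.nan
        if not np.isfinite(ms_e) or ms_e <= 0:
            # no residual variation: any effect is either exactly zero or sure
            ss_eff = max(ss_eff, 0.0)
            return (0.0, 1.0) if ss_eff <= 1e-12 else (np.inf, 0.0)
        f = (ss_eff / df_eff) / ms_e
        return float(f), float(sps.f.sf(f, df_eff, df_e))

    f_b, p_b = f_and_p(ss_group, df_group, ss_subj_err, df_subj_err)
    f_w, p_w = f_and_p(ss_within_lvl, df_within, ss_err, df_err)
    f_i, p_i = f_and_p(ss_inter, df_inter, ss_err, df_err)

    return MixedAnovaResult(
        f_between=f_b, p_between=p_b, f_within=f_w, p_within=p_w,
        f_interaction=f_i, p_interaction=p_i,
        df={"between": df_group, "subj_err": df_subj_err, "within": df_within,
            "interaction": df_inter, "err": df_err},
        ss={"total": float(ss_total), "between": float(ss_group),
            "subj_err": float(ss_subj_err), "within": float(ss_within_lvl),
            "interaction": float(ss_inter), "err": float(ss_err),
            "between_subjects": float(ss_between_subj)},
    )
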