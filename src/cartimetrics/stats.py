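"""The study's statistical battery.

Implements one-way repeated-measures ANOVA with the Tukey–Kramer post hoc
test (studentized-range distribution on the within-subject error term),
the exact Wilcoxon matched-pairs signed-rank test (full null distribution of
the positive-rank sum via a rank-polynomial convolution for n <= 25, normal
approximation with tie correction above), the two-tailed paired t-test,
Cohen's d on paired differences, and the normal-approximation minimum sample
size for a paired design.  The family-wise significance level used in study
reports is alpha = 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSamples",
    "TestResult",
    "rm_anova",
    "tukey_kramer",
    "wilcoxon_signed_rank",
    "paired_t",
    "cohens_d_paired",
    "min_sample_size",
    "signed_rank_distribution",
]

DEFAULT_ALPHA = 0.01
EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedSamples:
    """Complete subjects x conditions value matrix for within-subject tests."""

    subjects: list
    conditions: list
    values: np.ndarray  # shape (n_subjects, n_conditions)
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if len(self.subjects) != n or len(self.conditions) != k:
            raise ValueError("labels must match the value matrix")
        if k < 2:
            raise ValueError("need at least two conditions")
        if n < 3:
            raise ValueError("need at least three subjects")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: tuple[float, ...] | float | None = None
    adjusted_p: dict[tuple, float] = field(default_factory=dict)
    unadjusted_p: dict[tuple, float] = field(default_factory=dict)
    effect_size: float | None = None
    alpha: float = DEFAULT_ALPHA
    method: str = ""


def _anova_terms(values: np.ndarray):
    n, k = values.shape
    grand = values.mean()
    col_means = values.mean(axis=0)
    row_means = values.mean(axis=1)
    ss_cond = n * float(np.sum((col_means - grand) ** 2))
    ss_subj = k * float(np.sum((row_means - grand) ** 2))
    ss_tot = float(np.sum((values - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    return ss_cond, ss_err, df_cond, df_err


def rm_anova(samples: PairedSamples, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """One-way within-subject ANOVA: F = MS_condition / MS_error."""
    values = samples.values
    ss_cond, ss_err, df_cond, df_err = _anova_terms(values)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else math.inf
    else:
        f = ms_cond / ms_err
    p = 1.0 if ms_cond == 0 else float(sps.f.sf(f, df_cond, df_err)) if np.isfinite(f) else 0.0
    return TestResult(
        statistic=f, p_value=p, df=(df_cond, df_err), alpha=alpha, method="rm_anova"
    )


def tukey_kramer(samples: PairedSamples, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """All-pairs Tukey–Kramer comparisons on the RM-ANOVA error term.

    For each condition pair the studentized-range statistic is
    ``q = |m_i - m_j| / sqrt(MS_error / n)`` with the ANOVA error df; the
    adjusted p comes from the studentized-range distribution over all k
    conditions, the unadjusted p from the t distribution on the same
    contrast.
    """
    values = samples.values
    n, k = values.shape
    _, ss_err, _, df_err = _anova_terms(values)
    ms_err = ss_err / df_err
    col_means = values.mean(axis=0)
    adjusted, unadjusted = {}, {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = (samples.conditions[i], samples.conditions[j])
            diff = abs(col_means[i] - col_means[j])
            if ms_err == 0:
                p_adj = 1.0 if diff == 0 else 0.0
                p_un = p_adj
            else:
                q = diff / math.sqrt(ms_err / n)
                t = diff / math.sqrt(2.0 * ms_err / n)
                p_adj = float(sps.studentized_range.sf(q, k, df_err))
                p_un = float(2.0 * sps.t.sf(t, df_err))
            adjusted[pair] = min(1.0, p_adj)
            unadjusted[pair] = min(1.0, p_un)
    anova = rm_anova(samples, alpha)
    return TestResult(
        statistic=anova.statistic,
        p_value=anova.p_value,
        df=anova.df,
        adjusted_p=adjusted,
        unadjusted_p=unadjusted,
        alpha=alpha,
        method="tukey_kramer",
    )


def signed_rank_distribution(ranks) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum W+.

    ``ranks`` are the (possibly mid-) ranks of the nonzero |differences|.
    Works on doubled ranks so tied mid-ranks stay integral.  Returns the
    support of 2*W+ and its probabilities.
    """
    doubled = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    probs = counts / counts.sum()
    return np.arange(total + 1), probs


def wilcoxon_signed_rank(x, y, mode: str = "auto", alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are discarded (classical convention); tied absolute
    differences receive mid-ranks.  ``mode`` is 'exact' (full null
    distribution, n <= 25), 'approx' (normal with tie correction) or 'auto'.
    The degenerate all-zero case returns p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, df=None, alpha=alpha,
                          method="wilcoxon_degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"
    if mode == "exact":
        support2, probs = signed_rank_distribution(ranks)
        w2 = int(round(2 * w_pos))
        cdf = float(probs[support2 <= w2].sum())
        sf = float(probs[support2 >= w2].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
    elif mode == "approx":
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        z = (w_pos - mean) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")
    return TestResult(statistic=w_pos, p_value=p, df=None, alpha=alpha,
                      method=f"wilcoxon_{mode}")


def paired_t(x, y, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-tailed paired t-test on matched vectors."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = float(d.std(ddof=1))
    if sd == 0:
        p = 1.0 if d.mean() == 0 else 0.0
        stat = 0.0 if d.mean() == 0 else math.inf * np.sign(d.mean())
        return TestResult(statistic=float(stat), p_value=p, df=n - 1, alpha=alpha,
                          method="paired_t_degenerate")
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult(statistic=t, p_value=p, df=n - 1,
                      effect_size=cohens_d_paired(x, y), alpha=alpha,
                      method="paired_t")


def cohens_d_paired(x, y) -> float:
    """Cohen's d for paired data: mean difference over SD of the differences."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two pairs")
    sd = float(d.std(ddof=1))
    if sd == 0:
        if d.mean() == 0:
            return 0.0
        raise ValueError("zero difference SD with nonzero mean")
    return float(d.mean() / sd)


def min_sample_size(
    power: float,
    alpha: float,
    d: float,
    sided: str = "two",
    method: str = "normal",
) -> int:
    """Minimum n for a paired-difference test at the given power and effect.

    ``method='normal'`` uses the z-approximation
    ``n = ceil(((z_{1-alpha/2} + z_power) / d)^2)`` (``z_{1-alpha}`` for
    one-sided).  ``method='nct'`` searches for the smallest n whose exact
    noncentral-t power reaches the target; it is typically one or two
    subjects larger.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be positive")
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    tail = alpha / 2 if sided == "two" else alpha
    if method == "normal":
        z_a = sps.norm.ppf(1 - tail)
        z_b = sps.norm.ppf(power)
        return max(1, math.ceil(((z_a + z_b) / d) ** 2))
    if method == "nct":
        for n in range(2, 10_000):
            t_crit = sps.t.ppf(1 - tail, n - 1)
            achieved = float(sps.nct.sf(t_crit, n - 1, d * math.sqrt(n)))
            if sided == "two":
                achieved += float(sps.nct.cdf(-t_crit, n - 1, d * math.sqrt(n)))
            if achieved >= power:
                return n
        raise RuntimeError("sample size search did not converge")
    raise ValueError("method must be 'normal' or 'nct'")
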