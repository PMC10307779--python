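"""Group-level inferential tests, all two-tailed and uncorrected.

Every function returns a :class:`TestResult` with the statistic name, its
value, degrees of freedom where applicable, and a two-tailed p value.  The
conventions mirror how the results are reported: Student (pooled-variance)
unpaired t with df = n1+n2-2; within-subjects one-way ANOVA with
uncorrected integer degrees of freedom and no sphericity correction;
Mann-Whitney U summarised by a tie-corrected normal-approximation Z without
continuity correction; Pearson p values from the t transform
t = r*sqrt(n-2)/sqrt(1-r^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, InsufficientDataError

__all__ = [
    "TestResult", "one_sample_t", "paired_t", "unpaired_t",
    "rm_anova_one_way", "shapiro_wilk", "pearson", "p_from_r",
    "mann_whitney", "mann_whitney_u",
]


@dataclass
class TestResult:
    """One inferential test: statistic name/value, df, two-tailed p."""

    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Student one-sample t test of the mean against ``mu0``.

    A zero-variance sample equal to ``mu0`` everywhere is the exact null
    and returns t = 0, p = 1; a zero-variance sample elsewhere has an
    undefined statistic and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("one_sample_t needs n >= 2")
    s = x.std(ddof=1)
    df = x.size - 1
    if s == 0.0:
        if x.mean() == mu0:
            return TestResult("t", 0.0, float(df), 1.0)
        raise DegenerateSampleError("zero sample variance")
    t = (x.mean() - mu0) / (s / np.sqrt(x.size))
    return TestResult("t", float(t), float(df), float(2 * sps.t.sf(abs(t), df)))


def paired_t(x, y) -> TestResult:
    """Paired t test: one-sample t on the differences against zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("paired_t needs equal-length samples")
    return one_sample_t(x - y, 0.0)


def unpaired_t(x, y) -> TestResult:
    """Student (pooled-variance) two-sample t test, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("unpaired_t needs n >= 2 per group")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return TestResult("t", 0.0, float(df), 1.0)
        raise DegenerateSampleError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    return TestResult("t", float(t), float(df), float(2 * sps.t.sf(abs(t), df)))


def rm_anova_one_way(matrix) -> TestResult:
    """Within-subjects one-way ANOVA on a complete animals x sessions matrix.

    The total sum of squares is partitioned into subjects, treatment
    (sessions) and error; F = MS_treatment / MS_error on (k-1, (k-1)(n-1))
    degrees of freedom, with no sphericity correction.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InsufficientDataError("need >= 2 animals and >= 2 sessions")
    if np.isnan(m).any():
        raise InsufficientDataError("matrix contains missing cells")
    n, k = m.shape
    grand = m.mean()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_treat = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_treat
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0.0:
        if ss_treat == 0.0:
            return TestResult("F", 0.0, (float(df1), float(df2)), 1.0)
        raise DegenerateSampleError("zero error variance with nonzero effect")
    f = (ss_treat / df1) / ms_err
    return TestResult("F", float(f), (float(df1), float(df2)),
                      float(sps.f.sf(f, df1, df2)))


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (Royston approximation via scipy)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise InsufficientDataError("shapiro_wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample")
    w, p = sps.shapiro(x)
    return TestResult("W", float(w), None, float(min(max(p, 0.0), 1.0)))


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n (t transform, df = n-2)."""
    if n < 3:
        raise InsufficientDataError("p_from_r needs n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(abs(t), n - 2))


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-tailed t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("pearson needs equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return TestResult("r", r, float(x.size - 2), p_from_r(r, x.size))


def mann_whitney_u(x, y) -> float:
    """U statistic of the first sample, from midrank sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U with normal-approximation Z and no continuity correction.

    U is computed from midrank sums; the variance is tie-corrected.  The
    reported statistic is Z = (U1 - n1*n2/2) / sigma, where U1 belongs to
    the first sample, and p = 2 * (1 - Phi(|Z|)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("mann_whitney needs non-empty groups")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return TestResult("Z", 0.0, None, 1.0)
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    return TestResult("Z", float(z), None, float(2 * sps.norm.sf(abs(z))))
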