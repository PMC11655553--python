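"""Group-level inference battery: t-tests, Wilcoxon, correlations, outlier
fences, paired-design power, and Monte-Carlo calibration of the headline
contrast.

Conventions fixed here once: quartiles for the 1.5 x IQR rule use linear
interpolation between order statistics (the mainstream default); effect sizes
are Cohen's dz = mean(diff)/sd(diff) for paired designs and Cohen's d with the
pooled standard deviation for between-group contrasts; the Wilcoxon statistic
V is the sum of positive-difference ranks after dropping zero differences
(the convention of mainstream statistical environments), with an exact p-value
for n <= 25 and a continuity-corrected normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "OutlierMask",
    "iqr_outliers",
    "paired_t",
    "one_sample_t",
    "welch_t",
    "wilcoxon_signed_rank",
    "correlation_test",
    "power_paired_t",
    "paired_power",
    "paired_contrast_rejection_rate",
]


@dataclass(frozen=True)
class StatsResult:
    test: str
    statistic: float
    df: float
    p: float
    effect_size: float
    effect_size_type: str
    n: int
    outliers_removed: int = 0

    def __str__(self) -> str:  # report-friendly
        df = f"{self.df:g}" if self.df == int(self.df) else f"{self.df:.1f}"
        return (
            f"{self.test}: stat({df}) = {self.statistic:.3g}, p = {self.p:.3g}, "
            f"{self.effect_size_type} = {self.effect_size:.3g} (n = {self.n})"
        )


# ---------------------------------------------------------------------------
# outliers


@dataclass(frozen=True)
class OutlierMask:
    keep: np.ndarray  # True = retained
    fences: dict  # group level -> (lower, upper)
    variant: str

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


def iqr_outliers(values, grouping=None, variant: str = "raw-values") -> OutlierMask:
    """Tukey fences at Q1 - 1.5*IQR and Q3 + 1.5*IQR, per factor level.

    ``grouping`` assigns each observation to a factor level; fences are
    computed separately per level (pass None for a single group).  The
    ``paired-difference`` variant is a semantic tag for masks computed on
    real-minus-sham difference scores — the arithmetic is identical, the
    caller supplies the differences.
    """
    if variant not in ("raw-values", "paired-difference"):
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(values, dtype=float)
    g = np.zeros(len(x), dtype=object) if grouping is None else np.asarray(grouping, dtype=object)
    if len(g) != len(x):
        raise ValueError("values and grouping lengths differ")
    keep = np.ones(len(x), dtype=bool)
    fences = {}
    for level in pd_unique(g):
        idx = g == level
        if idx.sum() < 4:
            raise ValueError(f"need >= 4 observations per level, got {int(idx.sum())} in {level!r}")
        q1, q3 = np.quantile(x[idx], [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        fences[level] = (float(lo), float(hi))
        keep[idx] &= (x[idx] >= lo) & (x[idx] <= hi)
    return OutlierMask(keep=keep, fences=fences, variant=variant)


def pd_unique(arr):
    """Unique values preserving first appearance."""
    seen, out = set(), []
    for v in arr:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# t-tests


def paired_t(x, y, outliers_removed: int = 0) -> StatsResult:
    """Two-tailed paired t-test with Cohen's dz."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    return one_sample_t(d, 0.0, test="paired t", outliers_removed=outliers_removed)


def one_sample_t(x, popmean: float = 0.0, test: str = "one-sample t", outliers_removed: int = 0) -> StatsResult:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        delta = x.mean() - popmean
        if delta == 0.0:
            t, p, dz = 0.0, 1.0, 0.0
        else:
            import warnings

            warnings.warn("zero variance with nonzero mean difference: infinite t")
            t, p, dz = np.inf * np.sign(delta), 0.0, np.inf * np.sign(delta)
    else:
        t, p = sps.ttest_1samp(x, popmean)
        dz = (x.mean() - popmean) / sd
    return StatsResult(test, float(t), n - 1, float(p), float(dz), "dz", n, outliers_removed)


def welch_t(
    x=None,
    y=None,
    *,
    mean1=None,
    sd1=None,
    n1=None,
    mean2=None,
    sd2=None,
    n2=None,
    alternative: str = "two-sided",
    outliers_removed: int = 0,
) -> StatsResult:
    """Welch two-sample t-test from raw data or (mean, sd, n) summaries.

    Effect size is Cohen's d with the pooled standard deviation.  The
    Welch-Satterthwaite degrees of freedom are fractional.
    """
    if x is not None:
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), len(x)
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), len(y)
    if None in (mean1, sd1, n1, mean2, sd2, n2):
        raise ValueError("provide raw samples or complete summary statistics")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per sample")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False, alternative=alternative
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    sd_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = (mean1 - mean2) / sd_pooled if sd_pooled > 0 else np.nan
    return StatsResult(
        "Welch t", float(res.statistic), float(df), float(res.pvalue), float(d), "d", n1 + n2, outliers_removed
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def wilcoxon_signed_rank(x, y, outliers_removed: int = 0) -> StatsResult:
    """Signed-rank test; V = sum of positive-difference ranks (zeros dropped)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors required")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    # matched-pairs rank-biserial correlation as effect size
    total = n * (n + 1) / 2
    rb = 2 * v / total - 1
    return StatsResult(
        "Wilcoxon signed-rank (V)", v, np.nan, float(res.pvalue), float(rb), "rank-biserial r", n, outliers_removed
    )


# ---------------------------------------------------------------------------
# correlation


def correlation_test(x, y) -> StatsResult:
    """Pearson r with its t-test on df = n - 2."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    return StatsResult("Pearson correlation", float(t), n - 2, float(p), float(r), "r", n)


# ---------------------------------------------------------------------------
# power


def paired_power(n: int, dz: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a paired t-test via the noncentral t distribution."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = dz * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tc, df, ncp))


def power_paired_t(dz: float, power: float = 0.80, alpha: float = 0.05, tails: int = 2) -> int:
    """Smallest n whose paired t-test reaches the target power."""
    if dz <= 0:
        raise ValueError("dz must be > 0")
    if not (0 < power < 1):
        raise ValueError("power must lie in (0,1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while paired_power(n, dz, alpha, tails) < power:
        n += 1
        if n > 1_000_000:
            raise ValueError("target power unreachable at any feasible n")
    return n


def paired_contrast_rejection_rate(
    n: int,
    dz: float,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the paired contrast on difference scores.

    Each replicate draws per-subject paired differences of the adjustment-bias
    measure from N(dz, 1) (standardised units, so ``dz`` is the true paired
    effect size; dz = 0 gives the null) and applies the two-tailed paired
    contrast.  Returns the fraction of replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    d = rng.normal(dz, 1.0, size=(n_replicates, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    return float(np.mean(p < alpha))
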