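"""Statistical kernels of the multidomain association screen.

Pearson correlation with one- or two-tailed p-values, pooled-variance
two-sample comparison with a standardized mean difference, Benjamini–
Hochberg FDR control, and a Lilliefors-type normality check (Kolmogorov–
Smirnov distance against a normal with estimated parameters, Monte-Carlo
p-value).  Missing values are removed pairwise per test, so the effective
n may differ between variables and is always reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "FDRResult",
    "NormalityResult",
    "p_from_r",
    "pearson_test",
    "group_compare",
    "benjamini_hochberg",
    "lilliefors_normality",
]


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    t_stat: float
    df: int
    tails: str
    direction: str | None
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance t-test plus standardized mean difference.

    ``smd`` follows the convention (condition-present − condition-absent)
    divided by the pooled SD; swapping the groups flips its sign.
    """

    variable: str
    group_labels: tuple[str, str]
    n1: int
    n0: int
    mean1: float
    mean0: float
    sd1: float
    sd0: float
    t_stat: float
    p_value: float
    smd: float


@dataclass(frozen=True)
class FDRResult:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    q: float


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # KS distance D
    p_value: float  # reported value, capped at p_cap
    p_raw: float  # uncapped Monte-Carlo estimate
    n: int


def _tail_p(t: float, df: int, tails: str, direction: str | None) -> float:
    if tails == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tails != "one":
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    if direction not in ("positive", "negative"):
        raise ValueError("one-tailed test needs direction 'positive' or 'negative'")
    # pre-declared direction: p is the probability in that tail, so a sample
    # sign contradicting the hypothesis yields p > 0.5
    if direction == "negative":
        return float(sps.t.cdf(t, df))
    return float(sps.t.sf(t, df))


def p_from_r(
    r: float, n: int, tails: str = "two", direction: str | None = None
) -> float:
    """p-value implied by a Pearson r at sample size n.

    Uses t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom — the analytic
    link that lets a printed (r, n) pair be checked against its printed p.
    """
    if n < 3:
        raise ValueError("need n ≥ 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 for a finite t statistic")
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return _tail_p(float(t), df, tails, direction)


def pearson_test(
    x,
    y,
    tails: str = "two",
    direction: str | None = None,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson product-moment correlation with configurable tails.

    Pairs with a missing value in either vector are dropped; at least three
    complete pairs and nonzero variance in both vectors are required.  A
    perfect correlation (|r| = 1) is reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need ≥ 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")

    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.clip(r, -1.0, 1.0))
        t = np.inf * np.sign(r)
        p = 0.0  # deterministic relationship; p degenerates to 0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = _tail_p(float(t), df, tails, direction)
    return CorrelationResult(
        var_x=names[0],
        var_y=names[1],
        n=n,
        r=r,
        t_stat=float(t),
        df=df,
        tails=tails,
        direction=direction,
        p_value=p,
    )


def group_compare(
    values,
    group,
    variable: str = "value",
    group_labels: tuple[str, str] = ("present", "absent"),
    hedges: bool = False,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample comparison: Student t-test and Cohen's d (pooled SD).

    ``group`` is a boolean/0-1 indicator; rows where it or ``values`` is
    missing are dropped.  The SMD is (group-1 mean − group-0 mean) / pooled
    SD; ``hedges`` applies the small-sample bias correction, ``welch``
    switches the t-test to unequal variances (the SMD stays pooled).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=float)
    if values.shape != group.shape:
        raise ValueError("values and group must have equal length")
    keep = np.isfinite(values) & np.isfinite(group)
    values, group = values[keep], group[keep]
    g1 = values[group != 0]
    g0 = values[group == 0]
    n1, n0 = g1.size, g0.size
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs n ≥ 2, got {n1} and {n0}")

    s1 = float(np.std(g1, ddof=1))
    s0 = float(np.std(g0, ddof=1))
    pooled_var = ((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / (n1 + n0 - 2)
    if pooled_var == 0:
        raise ValueError("zero variance in both groups; t statistic undefined")

    t_stat, p = sps.ttest_ind(g1, g0, equal_var=not welch)
    if not np.isfinite(t_stat):
        raise ValueError("t statistic undefined for this grouping")

    smd = (float(np.mean(g1)) - float(np.mean(g0))) / np.sqrt(pooled_var)
    if hedges:
        df = n1 + n0 - 2
        smd *= 1.0 - 3.0 / (4.0 * df - 1.0)

    return GroupComparison(
        variable=variable,
        group_labels=group_labels,
        n1=n1,
        n0=n0,
        mean1=float(np.mean(g1)),
        mean0=float(np.mean(g0)),
        sd1=s1,
        sd0=s0,
        t_stat=float(t_stat),
        p_value=float(p),
        smd=float(smd),
    )


def benjamini_hochberg(p_values, q: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg step-up FDR control.

    Adjusted p-values are the standard step-up transform (monotone cummin
    from the largest rank, capped at 1); hypotheses with adjusted p ≤ q are
    rejected.  Results are returned in the input order; an empty input
    yields an empty result.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(p, p.copy(), np.zeros(0, dtype=bool), q)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(p_raw=p, p_adjusted=p_adj, rejected=p_adj <= q, q=q)


def _ks_distance_to_fitted_normal(x: np.ndarray) -> float:
    """Sup distance between the ECDF and the normal fitted by mean/SD."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors_normality(
    x, n_sim: int = 2000, seed: int | None = 0, p_cap: float = 0.200
) -> NormalityResult:
    """Kolmogorov–Smirnov normality check with estimated parameters.

    Because mean and SD are estimated from the sample, the classical KS
    null distribution does not apply (Lilliefors' correction); the p-value
    is estimated by simulating ``n_sim`` null samples of the same size.
    The reported p is capped at ``p_cap`` (0.200, the upper bound the
    standard look-up tables — and SPSS — report); the raw Monte-Carlo
    estimate is kept alongside.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 5:
        raise ValueError(f"need n ≥ 5, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    d_obs = _ks_distance_to_fitted_normal(x)

    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_sim, n))
    d_null = np.array([_ks_distance_to_fitted_normal(row) for row in null])
    p_raw = float((1 + np.count_nonzero(d_null >= d_obs)) / (n_sim + 1))
    return NormalityResult(
        statistic=d_obs, p_value=min(p_raw, p_cap), p_raw=p_raw, n=n
    )
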