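"""Branch-median trend statistics: the analysis core.

Per-branch medians of a per-protein metric are regressed on branch divergence
times (Mya, or log10 of it) by ordinary least squares; evolutionary rates are
read off the slope (a proportion metric's |slope|×100 is the usual
"% per protein per million years" phrasing). Also here: Wilcoxon rank-sum
comparisons between classes, per-amino-acid age correlations, 2×2 ratio
statistics, and extrapolation of a linear trend to a benchmark level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import BranchTable


@dataclass
class TrendFit:
    """OLS fit of branch medians against time."""

    slope: float  # metric units per My (or per log10 My)
    intercept: float
    p_value: float  # two-sided t test on the slope
    adj_r2: float
    n_points: int
    time_scale: str = "linear"  # "linear" | "log10"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a trend fit needs at least 3 points")
        if self.adj_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


@dataclass
class TwoByTwo:
    """Successes and totals for two groups."""

    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise ValueError("counts must satisfy 0 <= successes <= total")


def branch_medians(
    values: Mapping[str, Sequence[float]], branch_table: BranchTable
) -> List[Tuple[float, float]]:
    """Median per branch paired with its divergence time, ordered by time.

    Even-length lists take the mean of the central pair (numpy convention).
    """
    points: List[Tuple[float, float]] = []
    for branch, vals in values.items():
        if branch not in branch_table:
            raise KeyError(f"branch {branch!r} not in branch table")
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"branch {branch!r} has no values")
        points.append((branch_table.time_of(branch), float(np.median(vals))))
    points.sort()
    return points


def _ols(times: np.ndarray, medians: np.ndarray, time_scale: str) -> TrendFit:
    if times.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(times).size < times.size:
        raise ValueError("times must be distinct")
    res = stats.linregress(times, medians)
    n = times.size
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    p_value = float(res.pvalue)
    if math.isnan(p_value):  # zero residual AND zero slope variance (flat data)
        p_value = 1.0 if res.slope == 0 else 0.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p_value,
        adj_r2=float(adj_r2),
        n_points=int(n),
        time_scale=time_scale,
    )


def fit_linear_trend(points: Sequence[Tuple[float, float]]) -> TrendFit:
    """OLS of median on divergence time (My)."""
    pts = np.asarray(points, dtype=float)
    return _ols(pts[:, 0], pts[:, 1], "linear")


def fit_log10_trend(points: Sequence[Tuple[float, float]]) -> TrendFit:
    """OLS of median on log10(time); all times must be positive."""
    pts = np.asarray(points, dtype=float)
    if np.any(pts[:, 0] <= 0):
        raise ValueError("log10 trend requires strictly positive times")
    return _ols(np.log10(pts[:, 0]), pts[:, 1], "log10")


def time_to_benchmark(fit: TrendFit, benchmark: float) -> float:
    """Forward time (My) at which a linear trend reaches a benchmark level:
    t = (benchmark − intercept) / slope; the benchmark must lie ahead of the
    trend (t ≥ 0)."""
    if fit.time_scale != "linear":
        raise ValueError("extrapolation is defined for linear-time fits")
    if fit.slope == 0:
        raise ValueError("zero slope: benchmark unreachable")
    t = (benchmark - fit.intercept) / fit.slope
    if t < 0:
        raise ValueError(
            f"benchmark {benchmark} lies behind the trend (t = {t:.3g} My)"
        )
    return float(t)


_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> float:
    """Wilcoxon/Mann–Whitney rank-sum p-value.

    Exact null enumeration when n_x + n_y ≤ 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and combined.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


def per_aa_age_correlation(
    medians: Mapping[str, Sequence[Tuple[float, float]]]
) -> Dict[str, Tuple[float, float]]:
    """Pearson (r, p) between per-branch median amino-acid fractions and branch
    times. Positive r = the fraction grows with gene age. Amino acids with
    degenerate variance are flagged with (nan, nan)."""
    out: Dict[str, Tuple[float, float]] = {}
    for aa, points in medians.items():
        pts = np.asarray(points, dtype=float)
        if pts.shape[0] < 3:
            raise ValueError(f"{aa}: need at least 3 branches")
        t, m = pts[:, 0], pts[:, 1]
        if np.ptp(m) == 0 or np.ptp(t) == 0:
            out[aa] = (math.nan, math.nan)
            continue
        r, p = stats.pearsonr(t, m)
        out[aa] = (float(r), float(p))
    return out


def ratio_2x2(
    table: TwoByTwo,
    kind: str = "risk",
    continuity: float = 0.5,
    conf_level: float = 0.95,
) -> Tuple[float, float, float, float]:
    """Risk or odds ratio with a Wald CI on the log scale and a two-sided
    z-test p-value.

    Zero cells (or zero failure cells for odds) get a ``continuity`` (0.5)
    addition to every cell; set ``continuity=None`` to make that an error.
    """
    a, n1, b, n2 = float(table.a), float(table.n1), float(table.b), float(table.n2)
    c, d = n1 - a, n2 - b
    if kind == "risk":
        degenerate = a == 0 or b == 0
    elif kind == "odds":
        degenerate = a == 0 or b == 0 or c == 0 or d == 0
    else:
        raise ValueError(f"unknown ratio kind {kind!r}")
    if degenerate:
        if continuity is None:
            raise ValueError("zero cell without continuity correction")
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
        n1, n2 = a + c, b + d
    if kind == "risk":
        est = (a / n1) / (b / n2)
        se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    else:
        est = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    log_est = math.log(est)
    if se == 0:  # saturated margins (e.g. both rates 100%): no sampling spread
        return float(est), float(est), float(est), 1.0 if log_est == 0 else 0.0
    ci_low = math.exp(log_est - z * se)
    ci_high = math.exp(log_est + z * se)
    p = 2.0 * stats.norm.sf(abs(log_est) / se)
    return float(est), float(ci_low), float(ci_high), float(p)


def fisher_exact_p(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p for the same 2×2 layout (optional route)."""
    arr = [[table.a, table.n1 - table.a], [table.b, table.n2 - table.b]]
    return float(stats.fisher_exact(arr)[1])


def rate_percent_per_my(fit: TrendFit) -> float:
    """|slope| of a proportion metric expressed as % per protein per My."""
    return abs(fit.slope) * 100.0
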