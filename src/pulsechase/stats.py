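"""Phase-wise regression comparisons, rank tests and dilution ratios.

The trial's statistical layer: simple linear regressions of pooled
enrichment points over the uplabeling (day 0-7) and downlabeling (day 8-22)
windows, compared between treatment groups with the classical two-line
analysis of covariance (equality of slopes; equality of elevations given a
common slope), two-sided Mann-Whitney U tests for independent groups,
Wilcoxon signed-rank tests for paired blood-vs-sputum comparisons, and the
day-7-referenced dilution-ratio series used to contrast compartment
turnover.

Everything is computed from closed-form sums of squares and exact null
distributions built by counting, so each routine can be verified against a
brute-force enumeration or normal-equations oracle.  No multiplicity
correction is applied: p-values are per-comparison, as reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PhaseWindows",
    "WindowComparison",
    "RegressionComparison",
    "RankTestResult",
    "DilutionRatioSeries",
    "NotComputableError",
    "fit_line",
    "compare_phase_regressions",
    "rank_sum_test",
    "signed_rank_test",
    "dilution_ratio",
    "EXACT_RANKSUM_MAX_N",
    "EXACT_SIGNED_MAX_N",
]

#: largest combined sample size for which the Mann-Whitney null is enumerated
EXACT_RANKSUM_MAX_N = 16
#: largest number of nonzero pairs for which the signed-rank null is enumerated
EXACT_SIGNED_MAX_N = 15


class NotComputableError(ValueError):
    """A statistic whose preconditions the data do not meet."""


@dataclass(frozen=True)
class PhaseWindows:
    """Closed day intervals of the two labeling phases of the curve.

    A day-7 point belongs to the uplabeling window only.
    """

    up: tuple[float, float] = (0.0, 7.0)
    down: tuple[float, float] = (8.0, 22.0)

    def __post_init__(self) -> None:
        if self.up[0] > self.up[1] or self.down[0] > self.down[1]:
            raise ValueError("window bounds must be ordered")
        if self.up[1] >= self.down[0]:
            raise ValueError("uplabeling window must precede the downlabeling window")


def fit_line(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float, float, int]:
    """Closed-form OLS line through (day, enrichment) points.

    Returns (slope, intercept, residual_ss, n).
    """
    if len(points) < 2:
        raise NotComputableError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise NotComputableError("all points share one day: slope undefined")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = float(np.sum((y - slope * x - intercept) ** 2))
    return slope, intercept, rss, len(x)


@dataclass
class WindowComparison:
    """Two-line ANCOVA for one window: slopes, then elevations under a common slope."""

    window: str
    slope_a: float
    intercept_a: float
    slope_b: float
    intercept_b: float
    n_a: int
    n_b: int
    f_slope: float
    p_slope: float
    f_elev: float
    p_elev: float
    flags: list[str] = field(default_factory=list)


@dataclass
class RegressionComparison:
    """Up- and down-window comparisons between two groups.

    A window is ``None`` when either group has fewer than 3 points in it.
    """

    up: WindowComparison | None
    down: WindowComparison | None
    not_computable: dict[str, str] = field(default_factory=dict)


def _sums(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xbar, ybar = x.mean(), y.mean()
    return (
        float(np.sum((x - xbar) ** 2)),
        float(np.sum((x - xbar) * (y - ybar))),
        float(np.sum((y - ybar) ** 2)),
    )


def _f_pvalue(f: float, df1: int, df2: int) -> float:
    if not math.isfinite(f):
        return 0.0
    return float(sps.f.sf(f, df1, df2))


def _window_comparison(
    label: str,
    pts_a: list[tuple[float, float]],
    pts_b: list[tuple[float, float]],
) -> WindowComparison:
    xa = np.asarray([p[0] for p in pts_a], dtype=float)
    ya = np.asarray([p[1] for p in pts_a], dtype=float)
    xb = np.asarray([p[0] for p in pts_b], dtype=float)
    yb = np.asarray([p[1] for p in pts_b], dtype=float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise NotComputableError("a group has all points on one day")

    sxx_a, sxy_a, syy_a = _sums(xa, ya)
    sxx_b, sxy_b, syy_b = _sums(xb, yb)
    slope_a, slope_b = sxy_a / sxx_a, sxy_b / sxx_b
    intercept_a = float(ya.mean() - slope_a * xa.mean())
    intercept_b = float(yb.mean() - slope_b * xb.mean())
    n_a, n_b = len(xa), len(xb)
    n = n_a + n_b

    flags: list[str] = []
    # separate-slopes residual
    sse_sep = (syy_a - sxy_a**2 / sxx_a) + (syy_b - sxy_b**2 / sxx_b)
    df_sep = n - 4
    # common-slope residual
    slope_c = (sxy_a + sxy_b) / (sxx_a + sxx_b)
    sse_common = (syy_a + syy_b) - slope_c * (sxy_a + sxy_b)
    df_common = n - 3
    # single-line residual on the pooled points
    x_all = np.concatenate([xa, xb])
    y_all = np.concatenate([ya, yb])
    sxx_t, sxy_t, syy_t = _sums(x_all, y_all)
    sse_single = syy_t - (sxy_t**2 / sxx_t if sxx_t > 0 else 0.0)

    if df_sep <= 0:
        raise NotComputableError("too few points for the slope test")
    if sse_sep <= 0:
        # noise-free separable case: F is unbounded
        f_slope = math.inf if sse_common > sse_sep else 0.0
        flags.append("zero separate-fit residual: slope p-value at the 0 limit")
    else:
        f_slope = max(sse_common - sse_sep, 0.0) / (sse_sep / df_sep)
    p_slope = 1.0 if f_slope == 0.0 else _f_pvalue(f_slope, 1, df_sep)

    if sse_common <= 0:
        f_elev = math.inf if sse_single > sse_common else 0.0
        flags.append("zero common-slope residual: elevation p-value at the 0 limit")
    else:
        f_elev = max(sse_single - sse_common, 0.0) / (sse_common / df_common)
    p_elev = 1.0 if f_elev == 0.0 else _f_pvalue(f_elev, 1, df_common)
    if p_slope < 0.05:
        flags.append(
            "slopes differ: the elevation comparison assumes a common slope"
        )
    return WindowComparison(
        window=label,
        slope_a=slope_a,
        intercept_a=intercept_a,
        slope_b=slope_b,
        intercept_b=intercept_b,
        n_a=n_a,
        n_b=n_b,
        f_slope=float(f_slope),
        p_slope=float(np.clip(p_slope, 0.0, 1.0)),
        f_elev=float(f_elev),
        p_elev=float(np.clip(p_elev, 0.0, 1.0)),
        flags=flags,
    )


def compare_phase_regressions(
    group_a: Sequence[tuple[float, float]],
    group_b: Sequence[tuple[float, float]],
    windows: PhaseWindows = PhaseWindows(),
) -> RegressionComparison:
    """Compare up- and down-window regressions between two groups.

    Points are (phase-local day, enrichment) pooled across the subjects of
    each group.  Windows are closed intervals.  A window with fewer than 3
    points in either group is reported as not computable; the other window
    is still returned.
    """
    results: dict[str, WindowComparison | None] = {}
    not_comp: dict[str, str] = {}
    for label, (lo, hi) in (("up", windows.up), ("down", windows.down)):
        pa = [(d, v) for d, v in group_a if lo <= d <= hi]
        pb = [(d, v) for d, v in group_b if lo <= d <= hi]
        if len(pa) < 3 or len(pb) < 3:
            results[label] = None
            not_comp[label] = (
                f"need >= 3 points per group in the {label} window, "
                f"got {len(pa)} and {len(pb)}"
            )
            continue
        try:
            results[label] = _window_comparison(label, pa, pb)
        except NotComputableError as exc:
            results[label] = None
            not_comp[label] = str(exc)
    return RegressionComparison(
        up=results["up"], down=results["down"], not_computable=not_comp
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


@dataclass
class RankTestResult:
    """A two-sided nonparametric test result."""

    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    tie_correction: bool
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _ranksum_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of the rank sum of sample 1 (no ties).

    ``counts[s]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments in which sample 1's ranks sum to ``s``.  Dynamic-programming
    count over ranks 1..n1+n2 (distinct from the brute-force enumeration
    oracle used in the tests).
    """
    n = n1 + n2
    max_sum = n1 * n + 1
    # ways[k, s]: choose k ranks so far with sum s
    ways = np.zeros((n1 + 1, max_sum), dtype=np.int64)
    ways[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, :-r]
    return ways[n1]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution by counting when the combined sample size is at
    most 16 and the pooled data are tie-free; otherwise (or with ties) a
    midrank normal approximation with tie-corrected variance and continuity
    correction.  The reported statistic is U of the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise NotComputableError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= EXACT_RANKSUM_MAX_N and not has_ties:
        counts = _ranksum_null_counts(n1, n2)
        total = counts.sum()
        s = int(round(r1))
        p_low = counts[: s + 1].sum() / total
        p_high = counts[s:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankTestResult(
            statistic=u1, p_value=float(p), method="exact", tie_correction=False
        )

    flags = []
    if has_ties and n <= EXACT_RANKSUM_MAX_N:
        flags.append("ties present: exact enumeration replaced by approximation")
    mean_u = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return RankTestResult(
            statistic=u1,
            p_value=1.0,
            method="normal_approx",
            tie_correction=has_ties,
            flags=flags + ["all pooled values identical"],
        )
    z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return RankTestResult(
        statistic=u1,
        p_value=p,
        method="normal_approx",
        tie_correction=has_ties,
        flags=flags,
    )


def _signedrank_null_counts(ranks: Sequence[int]) -> np.ndarray:
    """Counts of the positive-rank sum W+ over all 2^n sign assignments."""
    total = int(sum(ranks))
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks:
        counts[r:] += counts[:-r].copy()
    return counts


def signed_rank_test(paired: Sequence[tuple[float, float]]) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on (a, b) pairs.

    Differences a-b of zero are dropped.  Exact sign-flip null by counting
    for up to 15 tie-free nonzero pairs, otherwise a tie-corrected normal
    approximation with continuity correction.  The statistic is the
    positive-rank sum W+.
    """
    if len(paired) == 0:
        raise NotComputableError("need at least one pair")
    d = np.asarray([a - b for a, b in paired], dtype=float)
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return RankTestResult(
            statistic=0.0,
            p_value=1.0,
            method="exact",
            tie_correction=False,
            flags=["all differences zero"],
        )
    n = len(nonzero)
    absd = np.abs(nonzero)
    ranks = _midranks(absd)
    w_plus = float(ranks[nonzero > 0].sum())

    _, tie_counts = np.unique(absd, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= EXACT_SIGNED_MAX_N and not has_ties:
        int_ranks = [int(round(r)) for r in ranks]
        counts = _signedrank_null_counts(int_ranks)
        total = counts.sum()  # 2^n
        w = int(round(w_plus))
        p_low = counts[: w + 1].sum() / total
        p_high = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankTestResult(
            statistic=w_plus, p_value=float(p), method="exact", tie_correction=False
        )

    flags = []
    if has_ties and n <= EXACT_SIGNED_MAX_N:
        flags.append("tied |differences|: exact enumeration replaced by approximation")
    mean_w = n * (n + 1) / 4.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return RankTestResult(
            statistic=w_plus,
            p_value=1.0,
            method="normal_approx",
            tie_correction=has_ties,
            flags=flags + ["degenerate variance"],
        )
    z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return RankTestResult(
        statistic=w_plus,
        p_value=p,
        method="normal_approx",
        tie_correction=has_ties,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# dilution ratios
# ---------------------------------------------------------------------------


@dataclass
class DilutionRatioSeries:
    """Enrichment relative to the (day-7) downlabeling-start maximum."""

    ref_day: float
    ref_value: float
    days: list[float]
    ratios: list[float]


def dilution_ratio(
    series: Sequence[tuple[float, float]],
    ref_day: float = 7.0,
    detection_threshold: float = 0.0005,
) -> DilutionRatioSeries:
    """Ratio of enrichment on each day after ``ref_day`` to the ``ref_day`` maximum.

    Raises :class:`NotComputableError` when no value exists at the reference
    day or the reference maximum does not exceed the detection threshold.
    """
    ref_vals = [v for d, v in series if d == ref_day]
    if not ref_vals:
        raise NotComputableError(f"no value at reference day {ref_day}")
    ref = max(ref_vals)
    if ref < detection_threshold or ref <= 0:
        raise NotComputableError(
            f"reference enrichment {ref} at day {ref_day} is below the "
            f"detection threshold {detection_threshold}"
        )
    after = sorted((d, v) for d, v in series if d >= ref_day)
    days = [d for d, _ in after]
    ratios = [v / ref for _, v in after]
    return DilutionRatioSeries(
        ref_day=ref_day, ref_value=ref, days=days, ratios=ratios
    )
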