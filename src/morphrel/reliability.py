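"""Test-retest reliability: ICC(1), category labels, mean deviations,
Mann-Whitney comparisons and exceedance curves.

The intraclass correlation is the one-way random-effects model for the
consistency of single measurements, ICC(1): with between-subject and
within-subject mean squares from a one-way ANOVA over a complete
n-subjects x k-sessions matrix,

    ICC(1) = (MS_B - MS_W) / (MS_B + (k - 1) MS_W)

with confidence limits from F = MS_B / MS_W and F-quantiles at
(n - 1, n(k - 1)) degrees of freedom (McGraw & Wong Case 1).  Estimates are
reported as computed, including negative values; the interpretation bands
are the Cicchetti guidelines (excellent >= .75, good .60-.74, fair .40-.59,
poor < .40).

Distributions of per-region reliability are compared with a two-sided
Mann-Whitney U test (normal approximation with tie and continuity
corrections), and summarized as exceedance curves: the proportion of regions
with reliability of at least x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SessionMatrix

logger = logging.getLogger(__name__)

CATEGORY_THRESHOLDS = (("excellent", 0.75), ("good", 0.60), ("fair", 0.40))


class DegenerateDataError(ValueError):
    """Statistic undefined on this input (e.g., zero variance, all ties)."""


# ---------------------------------------------------------------------------
# ICC(1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ms_between: float
    ms_within: float
    n_subjects: int
    k_sessions: int
    ci_lower: float
    ci_upper: float
    alpha: float
    category: str

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.icc <= self.ci_upper):
            raise ValueError("confidence interval must bracket the estimate")


def classify_icc(value: float) -> str:
    """Cicchetti interpretation band for an ICC value (boundaries inclusive
    at the lower edge: .75 excellent, .60 good, .40 fair, below .40 poor)."""
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    for name, lo in CATEGORY_THRESHOLDS:
        if value >= lo:
            return name
    return "poor"


def icc_oneway(m: SessionMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(1) with its McGraw-Wong Case-1 confidence interval."""
    y = m.values
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_between = k * float(((subj_means - grand) ** 2).sum())
    ss_within = float(((y - subj_means[:, None]) ** 2).sum())
    df_b, df_w = n - 1, n * (k - 1)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_b == 0 and ms_w == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)

    if ms_w == 0:
        lo = hi = 1.0
    else:
        f_obs = ms_b / ms_w
        f_low = f_obs / stats.f.ppf(1 - alpha / 2, df_b, df_w)
        f_up = f_obs * stats.f.ppf(1 - alpha / 2, df_w, df_b)
        lo = (f_low - 1) / (f_low + k - 1)
        hi = (f_up - 1) / (f_up + k - 1)
    return ICCResult(
        icc=float(icc),
        ms_between=ms_b,
        ms_within=ms_w,
        n_subjects=n,
        k_sessions=k,
        ci_lower=float(lo),
        ci_upper=float(hi),
        alpha=alpha,
        category=classify_icc(float(icc)),
    )


# ---------------------------------------------------------------------------
# Mean deviation
# ---------------------------------------------------------------------------

@dataclass
class MeanDeviationResult:
    per_subject: np.ndarray
    overall: float
    scheme: str


def mean_deviation(m: SessionMatrix, scheme: str = "from_mean") -> MeanDeviationResult:
    """Per-subject spread of the k session values.

    ``from_mean`` (default): mean absolute deviation of each subject's
    sessions from that subject's own mean.  ``pairwise``: mean absolute
    difference over all session pairs, an alternative reading of the same
    summary.
    """
    y = m.values
    if scheme == "from_mean":
        per = np.abs(y - y.mean(axis=1, keepdims=True)).mean(axis=1)
    elif scheme == "pairwise":
        diffs = np.abs(y[:, :, None] - y[:, None, :])
        k = y.shape[1]
        iu = np.triu_indices(k, 1)
        per = diffs[:, iu[0], iu[1]].mean(axis=1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return MeanDeviationResult(per_subject=per, overall=float(per.mean()), scheme=scheme)


# ---------------------------------------------------------------------------
# Mann-Whitney comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    u_statistic: float
    z_value: float
    p_value: float
    n_a: int
    n_b: int


_EXACT_ENUM_LIMIT = 200_000  # max number of group assignments to enumerate


def _exact_two_sided_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Tie-aware exhaustive permutation p: P(|U - mu| >= |u_obs - mu|)."""
    from itertools import combinations

    n = len(ranks)
    mu = n_a * (n - n_a) / 2.0
    dev = abs(u_obs - mu)
    offset = n_a * (n_a + 1) / 2
    hits = total = 0
    for comb in combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compare_regions(
    icc_a: Sequence[float], icc_b: Sequence[float], method: str = "auto"
) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of two reliability distributions.

    The z value always comes from the normal approximation with tie-corrected
    variance and continuity correction (the form in which such comparisons
    are reported).  The p-value is exact (tie-aware exhaustive enumeration of
    group assignments) for small samples under ``method="auto"``, where the
    normal approximation is visibly off; for region-scale samples the
    asymptotic p is used.  U is reported in the min-U convention.
    """
    a = np.asarray(list(icc_a), dtype=float)
    b = np.asarray(list(icc_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values tied across both groups")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b

    ranks = stats.rankdata(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma = np.sqrt(n_a * n_b / 12.0 * ((n + 1) - tie_term))
    if sigma == 0:
        raise DegenerateDataError("zero variance in the rank distribution")
    # continuity-corrected two-sided z from the larger U
    z = max((max(u_a, u_b) - mu - 0.5) / sigma, 0.0)

    from math import comb as n_choose_k

    if method == "exact" or (method == "auto" and n_choose_k(n, n_a) <= _EXACT_ENUM_LIMIT):
        p = _exact_two_sided_p(ranks, n_a, u_a)
    elif method in ("auto", "asymptotic"):
        p = min(1.0, 2.0 * stats.norm.sf(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        u_statistic=float(u_min), z_value=float(z), p_value=float(p), n_a=n_a, n_b=n_b
    )


# ---------------------------------------------------------------------------
# Exceedance curves
# ---------------------------------------------------------------------------

def exceedance_cdf(
    iccs: Sequence[float], grid: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of values >= x, evaluated on ``grid`` (default: the sorted
    sample points).  Right-continuous complement of the empirical CDF."""
    values = np.sort(np.asarray(list(iccs), dtype=float))
    if values.size == 0:
        raise ValueError("need at least one value")
    x = values if grid is None else np.asarray(list(grid), dtype=float)
    prop = 1.0 - np.searchsorted(values, x, side="left") / values.size
    return x, prop


# ---------------------------------------------------------------------------
# Report orchestration
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    table: pd.DataFrame
    comparisons: pd.DataFrame
    results: dict


def reliability_report(
    matrices: Iterable[SessionMatrix],
    alpha: float = 0.05,
    compare: Sequence[tuple[str, str]] | None = None,
    regional_iccs: dict[str, Sequence[float]] | None = None,
) -> ReliabilityReport:
    """Per-metric ICC table plus optional pairwise regional comparisons.

    ``regional_iccs`` maps metric names to lists of per-region ICCs; the
    pairs in ``compare`` (default: all pairs) are tested with
    :func:`compare_regions`.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one session matrix")
    rows, results = [], {}
    for m in matrices:
        res = icc_oneway(m, alpha=alpha)
        dev = mean_deviation(m)
        results[m.metric_name] = res
        rows.append(
            {
                "metric": m.metric_name,
                "n_subjects": res.n_subjects,
                "k_sessions": res.k_sessions,
                "icc": res.icc,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "category": res.category,
                "mean_deviation": dev.overall,
            }
        )
    table = pd.DataFrame(rows)

    comp_rows = []
    if regional_iccs:
        names = list(regional_iccs)
        if compare is None:
            compare = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        for name_a, name_b in compare:
            c = compare_regions(regional_iccs[name_a], regional_iccs[name_b])
            comp_rows.append(
                {
                    "metric_a": name_a,
                    "metric_b": name_b,
                    "u": c.u_statistic,
                    "z": c.z_value,
                    "p": c.p_value,
                    "n_a": c.n_a,
                    "n_b": c.n_b,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows, columns=["metric_a", "metric_b", "u", "z", "p", "n_a", "n_b"]
    )
    return ReliabilityReport(table=table, comparisons=comparisons, results=results)


__all__ = [
    "ICCResult",
    "MeanDeviationResult",
    "ComparisonResult",
    "ReliabilityReport",
    "DegenerateDataError",
    "classify_icc",
    "icc_oneway",
    "mean_deviation",
    "compare_regions",
    "exceedance_cdf",
    "reliability_report",
]
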