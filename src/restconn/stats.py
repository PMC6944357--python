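"""Two-group nonparametric comparisons with multiple-testing control.

Nodal graph metrics are compared between group matrices with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test under the tie-corrected
normal approximation without continuity correction, adjusted across
nodes/metrics by Benjamini-Hochberg FDR.  Counts of admitted triangles
are compared with the chi-square goodness-of-fit test against equal
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError


@dataclass(frozen=True)
class GroupComparisonResult:
    """One test row: statistic, df (chi-square only), raw and adjusted p."""

    test: str
    metric: str
    scope: str
    statistic: float
    df: int | None
    p_value: float
    p_fdr: float | None = None


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided rank-sum Z and p for independent samples.

    Normal approximation with tie correction and no continuity
    correction: Z = (R1 - n1(n+1)/2) / sigma, where R1 is the rank sum of
    ``x`` and sigma includes the tie term.  All observations tied across
    both samples is degenerate and returns (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 1.0
    z = (r1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_equal_prob(counts) -> tuple[float, int, float]:
    """Chi-square goodness of fit against equal expected counts.

    Returns (chi2, df, p) with df = k - 1.  All-zero counts are
    degenerate and return (0, k-1, 1).
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ParameterError("need at least two categories")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ParameterError("counts must be nonnegative integers")
    df = int(c.size - 1)
    if c.sum() == 0:
        return 0.0, df, 1.0
    chi2, p = sps.chisquare(c)
    return float(chi2), df, float(p)


def compare_nodal_metrics(
    metrics_a: dict[str, np.ndarray],
    metrics_b: dict[str, np.ndarray],
    scope: str,
) -> list[GroupComparisonResult]:
    """Rank-sum comparison of each nodal metric between two group graphs.

    One observation per node, per the group-matrix design; BH-FDR is
    applied within this (metric x scope) family and the family size is
    len(metrics_a).  Descriptive, not subject-level, inference.
    """
    if metrics_a.keys() != metrics_b.keys():
        raise ParameterError("both groups must provide the same metrics")
    rows = []
    for name in metrics_a:
        z, p = ranksum_test(metrics_a[name], metrics_b[name])
        rows.append(GroupComparisonResult("ranksum", name, scope, z, None, p))
    adj = bh_fdr([r.p_value for r in rows])
    return [
        GroupComparisonResult(r.test, r.metric, r.scope, r.statistic, r.df, r.p_value, float(q))
        for r, q in zip(rows, adj)
    ]
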