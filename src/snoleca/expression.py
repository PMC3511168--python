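"""Expression breadth (Shannon entropy) and host/non-host comparison.

A gene's breadth of expression over k tissues is the Shannon entropy
S = −Σ pᵢ ln pᵢ (nats) of its tissue proportions pᵢ = Eᵢ/T, T = Σ Eᵢ;
S ranges from 0 (single tissue) to ln k (uniform).  snoRNA host genes
are compared against non-host genes with a Mann–Whitney rank-sum test
whose null distribution is enumerated exactly (midranks, full subset
distribution via dynamic programming) for small samples and otherwise
approximated normally with tie-corrected variance and continuity
correction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Sided",
    "RankSumResult",
    "expression_entropy",
    "median_signal",
    "rank_sum_test",
    "compare_host_vs_nonhost",
]


class Sided(str, enum.Enum):
    TWO_SIDED = "two-sided"
    GREATER = "greater"  # first group tends larger
    LESS = "less"


@dataclass
class RankSumResult:
    u_statistic: float  # U of the first group
    z: float | None  # None when the exact null was enumerated
    p_value: float
    n1: int
    n2: int
    sided: Sided
    exact: bool


def expression_entropy(signals) -> float:
    """Shannon entropy S = −Σ pᵢ ln pᵢ (nats) of the tissue proportions;
    zero-signal tissues contribute 0 by the limit convention."""
    e = np.asarray(signals, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("signals must be a nonempty 1-D vector")
    if np.any(e < 0):
        raise ValueError("negative expression signal")
    total = e.sum()
    if total == 0:
        raise ValueError("all-zero profile: entropy undefined")
    p = e / total
    p = p[p > 0]  # filter after normalising: tiny signals can underflow to 0
    return float(-(p * np.log(p)).sum())


def median_signal(signals: pd.Series, duplicate_map: dict[str, str] | None = None) -> float:
    """Median signal over tissue groups, averaging within duplicate
    groups first (e.g. collapsing brain subsamples); the default map is
    the identity (every tissue its own group)."""
    if len(signals) == 0:
        raise ValueError("empty profile")
    s = pd.Series(signals, dtype=float)
    groups = s.index.map(lambda t: (duplicate_map or {}).get(t, t))
    return float(s.groupby(groups).mean().median())


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, u_obs: float, sided: Sided) -> float:
    """Exact null distribution of U over all C(N, n1) group assignments.

    ``ranks2`` are midranks scaled by 2 (integers).  A subset-sum DP
    counts assignments by rank total; with ties the distribution is the
    permutation distribution of the observed rank multiset.
    """
    n = len(ranks2)
    max_sum = int(ranks2.sum())
    # dp[k][s] = number of size-k subsets with scaled rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n1, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    sums = np.arange(max_sum + 1)
    # U for a subset with scaled rank sum s: U = s/2 - n1(n1+1)/2
    u_vals = sums / 2.0 - n1 * (n1 + 1) / 2.0
    n2 = n - n1
    if sided is Sided.GREATER:
        p = counts[u_vals >= u_obs - 1e-9].sum() / total
    elif sided is Sided.LESS:
        p = counts[u_vals <= u_obs + 1e-9].sum() / total
    else:
        mid = n1 * n2 / 2.0
        dev = abs(u_obs - mid)
        p = counts[np.abs(u_vals - mid) >= dev - 1e-9].sum() / total
    return float(min(p, 1.0))


def rank_sum_test(
    a, b, sided: Sided | str = Sided.TWO_SIDED, exact_limit: int = 400
) -> RankSumResult:
    """Mann–Whitney rank-sum test of two entropy samples.

    The U statistic of the first sample is computed with midranks for
    ties.  When n1·n2 ≤ ``exact_limit`` the p-value comes from the
    exact permutation distribution; otherwise from the normal
    approximation with tie-corrected variance and continuity
    correction.
    """
    sided = Sided(sided)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(len(combined))
    ranks[order] = np.arange(1, len(combined) + 1)
    # midranks for ties
    for v in np.unique(combined):
        mask = combined == v
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 * n2 <= exact_limit:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_rank_sum_p(ranks2, n1, u, sided)
        return RankSumResult(u, None, p, n1, n2, sided, exact=True)

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    mean = n1 * n2 / 2.0
    if var == 0:
        z, p = 0.0, 1.0
    else:
        from scipy.stats import norm

        if sided is Sided.GREATER:
            z = (u - mean - 0.5) / math.sqrt(var)
            p = float(norm.sf(z))
        elif sided is Sided.LESS:
            z = (u - mean + 0.5) / math.sqrt(var)
            p = float(norm.cdf(z))
        else:
            z = (u - mean - math.copysign(0.5, u - mean)) / math.sqrt(var) if u != mean else 0.0
            p = float(min(2 * norm.sf(abs(z)), 1.0))
    return RankSumResult(u, z, p, n1, n2, sided, exact=False)


def compare_host_vs_nonhost(
    matrix: pd.DataFrame,
    host_genes: set[str],
    sided: Sided | str = Sided.GREATER,
    duplicate_map: dict[str, str] | None = None,
) -> dict:
    """Entropy comparison of snoRNA host genes vs all other genes.

    ``matrix`` is gene × tissue; the primary report is one-sided
    (hosts more broadly expressed).  Returns the rank-sum result plus
    per-group entropy and median-signal summaries.
    """
    if not host_genes:
        raise ValueError("empty host gene set")
    missing = host_genes - set(matrix.index)
    if missing:
        raise KeyError(f"host genes absent from matrix: {sorted(missing)[:5]}")
    entropies = matrix.apply(lambda row: expression_entropy(row.values), axis=1)
    medians = matrix.apply(lambda row: median_signal(row, duplicate_map), axis=1)
    is_host = matrix.index.isin(host_genes)
    host_s, nonhost_s = entropies[is_host], entropies[~is_host]
    if len(nonhost_s) == 0:
        raise ValueError("no non-host genes in matrix")
    result = rank_sum_test(host_s.values, nonhost_s.values, sided)
    return {
        "rank_sum": result,
        "n_host": int(is_host.sum()),
        "n_nonhost": int((~is_host).sum()),
        "host_median_entropy": float(host_s.median()),
        "nonhost_median_entropy": float(nonhost_s.median()),
        "host_median_signal": float(medians[is_host].median()),
        "nonhost_median_signal": float(medians[~is_host].median()),
        "entropies": entropies,
    }
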