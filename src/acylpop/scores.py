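"""Deleteriousness-score comparisons between variant sets.

The Mann-Whitney U test here enumerates the exact permutation distribution
of U over the observed value multiset, which stays valid under ties —
deleteriousness scores routinely pile up at 1.0, where tabulated no-tie
critical values are wrong.  Above the exact-mode size bound the normal
approximation with midranks and tie correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .model import Cohort, VariantRecord
from .qc import allele_frequency

__all__ = [
    "ScoreComparison",
    "mann_whitney_exact",
    "chi2_two_proportions",
    "score_frequency_table",
]

EXACT_LIMIT = 20


@dataclass
class ScoreComparison:
    """Mann-Whitney comparison of two score samples."""

    n_x: int
    n_y: int
    u: float
    p_one_sided: float
    p_two_sided: float
    exact: bool
    ties_present: bool


def _u_from_ranks(ranks: np.ndarray, n_x: int) -> float:
    """U for group X from pooled midranks (X occupying the first n_x slots)."""
    r1 = ranks[:n_x].sum()
    return float(r1 - n_x * (n_x + 1) / 2)


def mann_whitney_exact(xs, ys, force_approx: bool = False) -> ScoreComparison:
    """Mann-Whitney U with an exact tie-aware permutation p-value.

    U counts pairs where x > y (ties contributing ½ via midranks).  For
    combined samples of at most 20 observations the p-value enumerates all
    C(n_x+n_y, n_x) assignments of the pooled value multiset; one-sided is
    P(U ≥ U_obs), two-sided is P(|U − n_x·n_y/2| ≥ |U_obs − n_x·n_y/2|).
    Larger samples fall back to the normal approximation with tie
    correction.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both score groups must be non-empty")
    n_x, n_y = xs.size, ys.size
    pooled = np.concatenate([xs, ys])
    ranks = stats.rankdata(pooled)
    u_obs = _u_from_ranks(ranks, n_x)
    ties = len(np.unique(pooled)) < pooled.size
    n = n_x + n_y
    if n <= EXACT_LIMIT and not force_approx:
        center = n_x * n_y / 2
        total = comb(n, n_x)
        ge = extreme = 0
        for subset in combinations(range(n), n_x):
            u = float(ranks[list(subset)].sum() - n_x * (n_x + 1) / 2)
            if u >= u_obs - 1e-9:
                ge += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-9:
                extreme += 1
        return ScoreComparison(
            n_x=n_x, n_y=n_y, u=u_obs,
            p_one_sided=ge / total,
            p_two_sided=min(1.0, extreme / total),
            exact=True, ties_present=ties,
        )
    # normal approximation with tie correction
    mu = n_x * n_y / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_x * n_y / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return ScoreComparison(n_x, n_y, u_obs, 1.0, 1.0, False, ties)
    z = (u_obs - mu) / sqrt(sigma2)
    p_one = float(stats.norm.sf(z))
    p_two = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return ScoreComparison(n_x, n_y, u_obs, p_one, p_two, False, ties)


def chi2_two_proportions(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson χ² (1 df) on the 2×2 allele-count table; returns (χ², p).

    Optional Yates continuity correction.  A table with a zero margin
    (e.g. both groups all-successes) is undefined and raises.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("counts must satisfy 0 <= k <= n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin table: chi-square undefined")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def score_frequency_table(
    variants: list[VariantRecord],
    cohorts: dict[str, Cohort],
    score: str = "polyphen2",
) -> pd.DataFrame:
    """Tidy long-format (variant, population, frequency, score) table.

    One row per variant × cohort, with the derived-allele frequency from
    :func:`acylpop.qc.allele_frequency` and the requested deleteriousness
    score (NaN when a variant has none).  No statistics are computed.
    """
    rows = []
    for pop, cohort in cohorts.items():
        for v in variants:
            try:
                j = cohort.variant_index(v.key)
            except KeyError:
                continue
            freq, _, _ = allele_frequency(cohort, j)
            rows.append(
                {
                    "variant": v.label,
                    "gene": v.gene,
                    "population": pop,
                    "frequency": freq,
                    "score": (v.scores or {}).get(score, np.nan),
                }
            )
    return pd.DataFrame(
        rows, columns=["variant", "gene", "population", "frequency", "score"]
    )
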