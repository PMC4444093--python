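"""Wright-style F-statistics between two populations, with randomization tests.

Four per-variant FST estimators are provided, because published values in
this literature rarely state which was used and the standard formulas can
differ appreciably at extreme frequency contrasts:

* ``wright`` — (HT − HS)/HT with the *unweighted* pooled frequency;
* ``nei_gst`` — the same with sample-size-weighted pooling;
* ``weir_cockerham`` — θ = a/(a+b+c) from the two-population variance
  components (observed heterozygosity used when genotype counts are
  supplied, HWE-expected otherwise);
* ``hudson`` — the ratio-of-moments estimator (sample sizes in
  chromosomes).

FIS is 1 − H_obs/H_exp with the small-sample-unbiased expected
heterozygosity 2pq·2N/(2N−1) by default.  Monomorphic sites are undefined
(returned as NaN and excluded from multi-locus summaries, never coerced
to 0).  Significance is by randomization: population labels are permuted
for FST; alleles are re-paired within the population for FIS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, Cohort

ESTIMATORS = ("wright", "nei_gst", "weir_cockerham", "hudson")

__all__ = [
    "ESTIMATORS",
    "FstResult",
    "fst_per_variant",
    "fis_per_variant",
    "multilocus_fst",
    "fst_randomization_test",
    "fis_randomization_test",
    "cohort_fst",
]


@dataclass
class FstResult:
    """One per-variant estimate, with W-C variance components when defined."""

    estimate: float
    estimator: str
    components: tuple[float, float, float] | None = None  # (a, b, c)


def _wc_components(
    p1: float, n1: int, p2: float, n2: int,
    h1: float | None, h2: float | None,
) -> tuple[float, float, float]:
    """Weir–Cockerham (1984) variance components for two populations.

    *n* in individuals; *h* the observed heterozygote proportion (defaults
    to the HWE expectation 2pq).
    """
    r = 2
    if h1 is None:
        h1 = 2 * p1 * (1 - p1)
    if h2 is None:
        h2 = 2 * p2 * (1 - p2)
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (
        s2
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def fst_per_variant(
    p1: float,
    n1: int,
    p2: float,
    n2: int,
    het_obs: tuple[float, float] | None = None,
    estimator: str = "weir_cockerham",
) -> FstResult:
    """Per-variant FST between two populations.

    Parameters
    ----------
    p1, p2
        Derived-allele frequencies; ``n1, n2`` sample sizes in individuals
        (≥ 2 each).
    het_obs
        Optional observed heterozygote proportions (population 1, 2); used
        by the Weir–Cockerham estimator only.
    estimator
        One of ``wright``, ``nei_gst``, ``weir_cockerham``, ``hudson``.

    A site monomorphic for the same allele in both populations is undefined
    and returns NaN.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 individuals per population")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    if p1 == p2 and p1 in (0.0, 1.0):
        return FstResult(float("nan"), estimator)

    if estimator in ("wright", "nei_gst"):
        if estimator == "wright":
            p_bar = (p1 + p2) / 2
            hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        else:
            p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
            hs = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / (n1 + n2)
        ht = 2 * p_bar * (1 - p_bar)
        return FstResult(
            float("nan") if ht == 0 else (ht - hs) / ht, estimator
        )
    if estimator == "hudson":
        m1, m2 = 2 * n1, 2 * n2  # chromosomes
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (m1 - 1)
            - p2 * (1 - p2) / (m2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return FstResult(float("nan") if den == 0 else num / den, estimator)
    h1, h2 = het_obs if het_obs is not None else (None, None)
    a, b, c = _wc_components(p1, n1, p2, n2, h1, h2)
    denom = a + b + c
    est = float("nan") if denom <= 0 else a / denom
    return FstResult(est, estimator, components=(a, b, c))


def fis_per_variant(
    hom_ref: int, het: int, hom_alt: int, unbiased: bool = True
) -> float:
    """Inbreeding coefficient FIS = 1 − H_obs/H_exp from genotype counts.

    ``unbiased=True`` (default) uses H_exp = 2pq·2N/(2N−1); monomorphic
    samples are undefined (NaN).
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom_ref + het + hom_alt
    if n < 2:
        raise ValueError("need at least 2 individuals")
    p = (2 * hom_alt + het) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan")
    h_exp = 2 * p * (1 - p)
    if unbiased:
        h_exp *= 2 * n / (2 * n - 1)
    return 1.0 - (het / n) / h_exp


def multilocus_fst(
    results: list[FstResult], method: str = "ratio_of_sums"
) -> float:
    """Multi-locus FST summary over per-variant results.

    ``ratio_of_sums`` pools Weir–Cockerham variance components, Σa/Σ(a+b+c)
    (requires component-bearing results); ``arithmetic_mean`` averages the
    defined per-locus estimates.  Undefined (NaN) loci are excluded.
    """
    if method == "arithmetic_mean":
        vals = [r.estimate for r in results if np.isfinite(r.estimate)]
        if not vals:
            raise ValueError("no defined loci")
        return float(np.mean(vals))
    if method != "ratio_of_sums":
        raise ValueError(f"unknown method {method!r}")
    comps = [r.components for r in results if r.components is not None]
    if not comps:
        raise ValueError("ratio_of_sums needs Weir-Cockerham components")
    num = sum(a for a, _, _ in comps)
    den = sum(a + b + c for a, b, c in comps)
    if den <= 0:
        raise ValueError("ratio_of_sums undefined: component sum <= 0")
    return float(num / den)


def _obs_het(cohort: Cohort, j: int) -> tuple[float, int]:
    g = cohort.genotypes[:, j]
    called = g != MISSING
    n = int(called.sum())
    return (float((g[called] == 1).sum()) / n if n else float("nan")), n


def cohort_fst(
    cohort_a: Cohort,
    cohort_b: Cohort,
    estimator: str = "weir_cockerham",
) -> list[FstResult]:
    """Per-variant FST over the shared variant list of two cohorts."""
    keys = [v.key for v in cohort_a.variants]
    out = []
    for key in keys:
        ja = cohort_a.variant_index(key)
        jb = cohort_b.variant_index(key)
        fa, _, ca = _freq(cohort_a, ja)
        fb, _, cb = _freq(cohort_b, jb)
        h1, n1 = _obs_het(cohort_a, ja)
        h2, n2 = _obs_het(cohort_b, jb)
        out.append(
            fst_per_variant(fa, n1, fb, n2, het_obs=(h1, h2), estimator=estimator)
        )
    return out


def _freq(cohort: Cohort, j: int) -> tuple[float, int, int]:
    called = cohort.called_chromosomes(j)
    if called == 0:
        return float("nan"), 0, 0
    derived = cohort.derived_count(j)
    return derived / called, derived, called


def fst_randomization_test(
    cohort_a: Cohort,
    cohort_b: Cohort,
    statistic=None,
    n_rand: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Randomization p-value for a between-population statistic.

    *statistic* maps ``(cohort_a, cohort_b)`` to a scalar; the default is
    the multi-locus Weir–Cockerham ratio-of-sums FST.  Individuals are
    permuted between the population labels ``n_rand`` times and the
    two-sided empirical p-value ``(1 + #{|perm| ≥ |obs|})/(1 + n_rand)``
    (minimum ``1/(n_rand+1)``) is returned with the observed value.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if statistic is None:
        def statistic(a, b):
            return multilocus_fst(cohort_fst(a, b), "ratio_of_sums")

    observed = statistic(cohort_a, cohort_b)
    pooled = Cohort.concatenate([cohort_a, cohort_b])
    na = cohort_a.n_individuals
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(pooled.n_individuals)
        pa = pooled.subset_samples(perm[:na])
        pb = pooled.subset_samples(perm[na:])
        if abs(statistic(pa, pb)) >= abs(observed) - 1e-12:
            hits += 1
    return observed, (1 + hits) / (1 + n_rand)


def fis_randomization_test(
    cohort: Cohort,
    n_rand: int = 1000,
    seed: int = 0,
    unbiased: bool = True,
) -> tuple[float, float]:
    """Randomization test of mean FIS against 0 within one population.

    The observed statistic is the mean of defined per-variant FIS values.
    Each randomization re-pairs the alleles of every variant uniformly at
    random among individuals (destroying genotypic correlation while
    preserving allele counts), and the two-sided add-one empirical p-value
    is returned with the observed mean.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")

    def mean_fis(geno: np.ndarray) -> float:
        vals = []
        for j in range(geno.shape[1]):
            g = geno[:, j]
            g = g[g != MISSING]
            f = fis_per_variant(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()),
                unbiased=unbiased,
            )
            if np.isfinite(f):
                vals.append(f)
        return float(np.mean(vals)) if vals else float("nan")

    observed = mean_fis(cohort.genotypes)
    rng = np.random.default_rng(seed)
    hits = 0
    n = cohort.n_individuals
    for _ in range(n_rand):
        geno = np.empty_like(cohort.genotypes)
        for j in range(cohort.n_variants):
            g = cohort.genotypes[:, j]
            called = g != MISSING
            # expand to an allele vector, shuffle, re-pair
            vec = np.concatenate([
                np.ones(int(g[called].sum()), dtype=np.int8),
                np.zeros(2 * int(called.sum()) - int(g[called].sum()),
                         dtype=np.int8),
            ])
            rng.shuffle(vec)
            paired = vec.reshape(-1, 2).sum(axis=1)
            col = np.full(n, MISSING, dtype=np.int8)
            col[called] = paired
            geno[:, j] = col
        if abs(mean_fis(geno)) >= abs(observed) - 1e-12:
            hits += 1
    return observed, (1 + hits) / (1 + n_rand)
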