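"""Genotype-level quality control and cohort screening.

Covers the exome-QC genotype filters (depth ≥ 20, genotype quality ≥ 10,
alternate-read fraction ≥ 0.25 for calls carrying the ALT allele), allele
frequencies over called chromosomes, the Hardy-Weinberg exact test,
cross-platform genotype concordance, and identity-by-state / classical-MDS
ancestry-outlier screening.

The "variant frequency ≥ 25%" filter is interpreted as the per-genotype
alternate-read fraction (the standard exome-QC reading), applied only to
heterozygous and hom-alt calls — not as a cohort-level minor-allele
frequency cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MISSING, Cohort

__all__ = [
    "QCThresholds",
    "filter_genotypes",
    "allele_frequency",
    "hwe_exact_test",
    "concordance",
    "ibs_mds",
    "flag_ancestry_outliers",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-genotype QC cutoffs (all inclusive minima)."""

    min_depth: float = 20.0
    min_alt_fraction: float = 0.25
    min_gq: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_alt_fraction, self.min_gq) < 0:
            raise ValueError("QC thresholds must be nonnegative")


def filter_genotypes(
    cohort: Cohort, thresholds: QCThresholds = QCThresholds()
) -> tuple[Cohort, int]:
    """Mask genotypes failing any QC threshold; returns (cohort, n_masked).

    A genotype is kept only if every available metric passes: depth ≥
    min_depth, GQ ≥ min_gq, and — for calls carrying at least one ALT
    allele — alternate-read fraction ≥ min_alt_fraction.  Metrics that are
    absent (matrix missing or NaN at a call) do not mask.  Idempotent.
    """
    out = cohort.copy()
    fail = np.zeros(out.genotypes.shape, dtype=bool)
    if out.depth is not None:
        fail |= out.depth < thresholds.min_depth
    if out.gq is not None:
        fail |= out.gq < thresholds.min_gq
    if out.alt_fraction is not None:
        carries_alt = out.genotypes >= 1
        fail |= carries_alt & (out.alt_fraction < thresholds.min_alt_fraction)
    fail &= out.genotypes != MISSING
    out.genotypes[fail] = MISSING
    return out, int(fail.sum())


def allele_frequency(
    cohort: Cohort, variant: int | str
) -> tuple[float, int, int]:
    """Derived-allele frequency at a variant.

    Returns ``(frequency, derived_alleles, called_chromosomes)``; the
    denominator is the number of called chromosomes (missing genotypes are
    excluded), and counting is oriented by the variant's derived-allele
    flag.  Raises on an all-missing variant.
    """
    j = cohort.variant_index(variant)
    called = cohort.called_chromosomes(j)
    if called == 0:
        raise ValueError(f"variant {cohort.variants[j].label}: no called genotypes")
    derived = cohort.derived_count(j)
    return derived / called, derived, called


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (the standard exact-test convention).  Monomorphic
    samples return 1.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    m = min(2 * hom_ref + het, 2 * hom_alt + het)  # minor allele count
    if m == 0:
        return 1.0
    # log P(het | m, n) up to the common normalizer:
    # C(n; hr, het, ha) * 2^het  with ha = (m - het)/2 of the minor allele
    hets = np.arange(m % 2, m + 1, 2)
    ha = (m - hets) // 2
    hr = n - hets - ha
    valid = hr >= 0
    hets, ha, hr = hets[valid], ha[valid], hr[valid]
    lg = np.vectorize(math.lgamma)
    logp = (
        lg(n + 1)
        - lg(hr + 1)
        - lg(hets + 1)
        - lg(ha + 1)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("heterozygote count inconsistent with allele count")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def concordance(
    cohort_a: Cohort,
    cohort_b: Cohort,
    variant_class_partition: dict[str, list[str]],
) -> dict[str, float]:
    """Per-class genotype concordance between two platforms.

    *variant_class_partition* maps a class label (e.g. ``exonic``,
    ``intronic``) to variant keys present in both cohorts.  The rate for a
    class is matching non-missing genotype pairs / compared pairs over the
    shared samples.  Raises if no variant overlaps.
    """
    shared_samples = [s for s in cohort_a.samples if s in set(cohort_b.samples)]
    ia = [cohort_a.samples.index(s) for s in shared_samples]
    ib = [cohort_b.samples.index(s) for s in shared_samples]
    keys_a = {v.key: j for j, v in enumerate(cohort_a.variants)}
    keys_b = {v.key: j for j, v in enumerate(cohort_b.variants)}
    overlap = set(keys_a) & set(keys_b)
    if not overlap:
        raise ValueError("cohorts share no variants")
    rates: dict[str, float] = {}
    for cls, keys in variant_class_partition.items():
        matched = compared = 0
        for key in keys:
            if key not in overlap:
                continue
            ga = cohort_a.genotypes[ia, keys_a[key]]
            gb = cohort_b.genotypes[ib, keys_b[key]]
            ok = (ga != MISSING) & (gb != MISSING)
            compared += int(ok.sum())
            matched += int((ga[ok] == gb[ok]).sum())
        rates[cls] = matched / compared if compared else float("nan")
    return rates


def ibs_distance_matrix(cohort: Cohort) -> np.ndarray:
    """Allele-sharing distance d(i,j) = 1 - IBS(i,j)/2.

    IBS(i,j) is the mean over variants called in both individuals of the
    number of shared alleles, 2 - |g_i - g_j|.
    """
    g = cohort.genotypes.astype(float)
    g[cohort.genotypes == MISSING] = np.nan
    n = cohort.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i])  # (n, m)
        with np.errstate(invalid="ignore"):
            d[i] = np.nanmean(diff, axis=1) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(d: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centers the squared distances and eigen-decomposes; coordinates
    are deterministic up to sign, and the sign is fixed so each axis's
    largest-magnitude coordinate is positive.
    """
    n = d.shape[0]
    if dims > n:
        raise ValueError("more dimensions requested than individuals")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def ibs_mds(cohort: Cohort, dims: int = 2) -> np.ndarray:
    """Per-individual coordinates from classical MDS of the IBS distance."""
    if cohort.n_individuals < 3:
        raise ValueError("need at least 3 individuals for MDS")
    return classical_mds(ibs_distance_matrix(cohort), dims=dims)


def flag_ancestry_outliers(
    coords: np.ndarray,
    cluster_labels: list[str],
    k: float = 6.0,
) -> np.ndarray:
    """Flag individuals far from their claimed cluster's medoid.

    For each cluster, the medoid (member minimizing total distance to the
    others, on the first two axes) and the per-axis median absolute
    deviation (MAD, scaled by 1.4826 so that k·MAD ≈ k·σ under normal
    spread) are computed from all members claiming that label; an
    individual is flagged when it lies more than ``k·MAD`` from the medoid
    on axis 1 or axis 2.  Robust to a minority of planted outliers; clusters
    need ≥ 3 members.
    """
    coords = np.asarray(coords, dtype=float)[:, :2]
    labels = np.asarray(cluster_labels)
    flags = np.zeros(len(labels), dtype=bool)
    for cluster in np.unique(labels):
        idx = np.flatnonzero(labels == cluster)
        if len(idx) < 3:
            raise ValueError(f"cluster {cluster!r} has fewer than 3 members")
        pts = coords[idx]
        pair = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        medoid = pts[np.argmin(pair.sum(axis=1))]
        dev = np.abs(pts - medoid)
        mad = 1.4826 * np.median(dev, axis=0)
        if math.isinf(k):
            continue
        flags[idx] |= (dev > k * mad).any(axis=1)
    return flags
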