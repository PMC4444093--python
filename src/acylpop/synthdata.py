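"""Synthetic diploid cohort generators.

Three generators cover the statistical structure the downstream analyses
assume:

* :func:`simulate_cohort` — independent biallelic variants at specified
  derived-allele frequencies, either with *exact* allele counts
  (``round(2N·p)`` derived alleles placed in the Hardy-Weinberg-closest
  genotype configuration — the mode that makes burden statistics
  deterministic) or by i.i.d. Hardy-Weinberg sampling.
* :func:`simulate_haplotype_cohort` — individuals as i.i.d. draws of two
  haplotypes from a specified haplotype-frequency distribution, retaining
  the phased truth next to the unphased genotype matrix.
* :func:`simulate_admixed` — individuals whose per-variant derived-allele
  frequency is the λ-mixture of two source frequency profiles.

All generators take a mandatory integer seed and are reproducible
bit-for-bit given (seed, spec).  They model neither linkage between the
independent variants of :func:`simulate_cohort` nor sequencing error;
genotype matrices are complete (no missing calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Cohort, VariantRecord

__all__ = [
    "CohortSpec",
    "HaplotypeSpec",
    "simulate_cohort",
    "simulate_haplotype_cohort",
    "simulate_admixed",
]


@dataclass
class CohortSpec:
    """Recipe for an independent-variants cohort.

    Parameters
    ----------
    n_individuals
        Diploid cohort size N (≥ 1).
    variants
        List of ``(VariantRecord, derived-allele frequency)`` pairs.
    mode
        ``"exact_count"`` places exactly ``round(2N·p)`` derived alleles per
        variant; ``"hwe_sampling"`` draws genotypes i.i.d. from
        (q², 2pq, p²).
    seed
        Mandatory RNG seed.
    het_overrides
        Optional variant key → heterozygote count, overriding the
        HWE-rounded genotype configuration in exact_count mode (the
        published FIS table implies near-HWE configurations but the actual
        hom/het splits were not published, so they are exposed here).
    target_fis
        Optional inbreeding coefficient; when set, exact_count
        heterozygote counts are chosen closest to ``(1-FIS)·2pq·N``.
    """

    n_individuals: int
    variants: list[tuple[VariantRecord, float]]
    mode: str = "exact_count"
    seed: int = 0
    sample_prefix: str = "S"
    het_overrides: dict[str, int] = field(default_factory=dict)
    target_fis: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.mode not in ("exact_count", "hwe_sampling"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for rec, p in self.variants:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{rec.label}: frequency {p} outside [0, 1]")


@dataclass
class HaplotypeSpec:
    """Recipe for a linked-loci cohort drawn from a haplotype distribution.

    ``haplotypes`` maps allele strings (one character per locus, drawn from
    each locus's ref/alt alphabet) to frequencies summing to 1.
    """

    loci: list[VariantRecord]
    haplotypes: dict[str, float]
    n_individuals: int
    seed: int = 0
    sample_prefix: str = "H"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        total = sum(self.haplotypes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        L = len(self.loci)
        for h in self.haplotypes:
            if len(h) != L:
                raise ValueError(f"haplotype {h!r} length != {L} loci")
            for c, rec in zip(h, self.loci):
                if c not in (rec.ref, rec.alt):
                    raise ValueError(
                        f"haplotype {h!r}: allele {c!r} not in "
                        f"{{{rec.ref},{rec.alt}}} at {rec.label}"
                    )


def _exact_count_genotypes(
    n: int, p: float, rng: np.random.Generator, het_target: int | None
) -> np.ndarray:
    """Genotype column with exactly round(2n·p) derived alleles.

    Defaults to the HWE-closest configuration: hom-derived count rounded to
    ``n·p̂²`` with p̂ the realized frequency, heterozygotes making up the
    remainder.  Carriers are assigned to shuffled individuals so that
    genotypes are exchangeable across variants.
    """
    alleles = int(np.rint(2 * n * p))
    if not 0 <= alleles <= 2 * n:
        raise ValueError(f"allele count {alleles} not representable for N={n}")
    lo_hom = max(0, alleles - n)
    hi_hom = alleles // 2
    if het_target is not None:
        het = min(max(het_target, alleles - 2 * hi_hom), alleles - 2 * lo_hom)
        if (alleles - het) % 2:
            het += 1 if het < alleles - 2 * lo_hom else -1
        hom = (alleles - het) // 2
    else:
        p_hat = alleles / (2 * n)
        hom = int(np.rint(n * p_hat * p_hat))
        hom = min(max(hom, lo_hom), hi_hom)
    het = alleles - 2 * hom
    g = np.zeros(n, dtype=np.int8)
    g[:hom] = 2
    g[hom : hom + het] = 1
    rng.shuffle(g)
    return g


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort of unlinked biallelic variants per *spec*.

    Returns a complete (no missing calls) genotype matrix with the
    generating frequencies retained in ``truth_frequencies``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    cols = []
    for rec, p in spec.variants:
        if spec.mode == "exact_count":
            het_target = None
            if rec.key in spec.het_overrides:
                het_target = spec.het_overrides[rec.key]
            elif spec.target_fis is not None:
                het_target = int(np.rint((1 - spec.target_fis) * 2 * p * (1 - p) * n))
            cols.append(_exact_count_genotypes(n, p, rng, het_target))
        else:
            cols.append(rng.binomial(2, p, size=n).astype(np.int8))
    geno = (
        np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.int8)
    )
    # genotype codes count ALT copies; flip where derived != alt
    for j, (rec, _) in enumerate(spec.variants):
        if not rec.derived_is_alt:
            geno[:, j] = 2 - geno[:, j]
    return Cohort(
        variants=[rec for rec, _ in spec.variants],
        samples=[f"{spec.sample_prefix}{i:04d}" for i in range(n)],
        genotypes=geno,
        truth_frequencies={rec.key: p for rec, p in spec.variants},
    )


def simulate_haplotype_cohort(spec: HaplotypeSpec) -> Cohort:
    """Draw 2N haplotypes i.i.d. from the spec distribution and genotype them.

    The phased truth (haplotype index pair per individual) is retained in
    ``phased_haplotypes`` / ``haplotype_strings``; the genotype matrix is the
    unphased ALT-copy-number sum.
    """
    rng = np.random.default_rng(spec.seed)
    haps = list(spec.haplotypes)
    freqs = np.array([spec.haplotypes[h] for h in haps], dtype=float)
    freqs = freqs / freqs.sum()
    n = spec.n_individuals
    draws = rng.choice(len(haps), size=(n, 2), p=freqs)
    # allele matrix: haplotype index -> 0/1 codes per locus
    codes = np.array(
        [[1 if c == rec.alt else 0 for c, rec in zip(h, spec.loci)] for h in haps],
        dtype=np.int8,
    )
    geno = codes[draws[:, 0]] + codes[draws[:, 1]]
    return Cohort(
        variants=list(spec.loci),
        samples=[f"{spec.sample_prefix}{i:04d}" for i in range(n)],
        genotypes=geno.astype(np.int8),
        phased_haplotypes=draws,
        haplotype_strings=haps,
    )


def simulate_admixed(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    mixing: float,
    n: int,
    seed: int,
    sample_prefix: str = "ADX",
) -> Cohort:
    """Cohort of admixed individuals between two source frequency profiles.

    Each individual's per-variant derived-allele frequency is
    ``(1-λ)·p_A + λ·p_B`` (λ = *mixing*); genotypes are drawn under HWE at
    the mixed frequency.  Both specs must list the same variants in the
    same order.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing fraction must be in [0, 1]")
    keys_a = [rec.key for rec, _ in spec_a.variants]
    keys_b = [rec.key for rec, _ in spec_b.variants]
    if keys_a != keys_b:
        raise ValueError("specs do not share a variant list")
    mixed = CohortSpec(
        n_individuals=n,
        variants=[
            (rec, (1 - mixing) * pa + mixing * pb)
            for (rec, pa), (_, pb) in zip(spec_a.variants, spec_b.variants)
        ],
        mode="hwe_sampling",
        seed=seed,
        sample_prefix=sample_prefix,
    )
    return simulate_cohort(mixed)
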