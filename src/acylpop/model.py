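"""Shared domain types: variants, gene models, reference panels, cohorts.

The central container is :class:`Cohort`, an individuals × variants genotype
matrix (0/1/2 copies of the ALT allele, -1 for missing) with optional
per-genotype depth / genotype-quality / alternate-read-fraction matrices and,
for simulated data, the phased haplotype truth.  Allele counting is always
*derived-allele* oriented: each :class:`VariantRecord` carries an explicit
``derived_is_alt`` flag rather than assuming ALT = derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

CONSEQUENCE_CLASSES = ("missense", "synonymous", "splicing", "other")

MISSING = -1


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with its gene context and optional deleteriousness scores.

    ``scores`` maps score name (``polyphen2``, ``mutationtaster``) to a value
    in [0, 1].  ``name`` is the protein-level label used in reports
    (e.g. ``p.P479L``).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str = "other"
    rsid: str | None = None
    derived_is_alt: bool = True
    scores: Mapping[str, float] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"consequence {self.consequence!r} not in {CONSEQUENCE_CLASSES}"
            )
        if self.scores is not None:
            for k, v in self.scores.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"score {k}={v} outside [0, 1]")

    @property
    def key(self) -> str:
        """Canonical ``chrom:pos:ref:alt`` identifier."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def label(self) -> str:
        """Human-readable label: rsid, protein name, or the coordinate key."""
        return self.rsid or self.name or self.key


@dataclass(frozen=True)
class GeneModel:
    """A gene region (1-based, inclusive) with flanking slack for assignment."""

    gene: str
    chrom: str
    start: int
    end: int
    flank: int = 2000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            chrom == self.chrom
            and self.start - self.flank <= pos <= self.end + self.flank
        )


@dataclass
class PanelPopulation:
    """One reference population: chromosome count and derived-allele frequencies."""

    name: str
    chromosomes: int
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chromosomes <= 0 or self.chromosomes % 2:
            raise ValueError(
                f"{self.name}: chromosome count must be a positive even integer"
            )
        for k, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}/{k}: frequency {f} outside [0, 1]")

    def frequency(self, key: str, warn_missing: bool = False) -> float:
        if key not in self.frequencies:
            if warn_missing:
                warnings.warn(
                    f"variant {key} absent from panel {self.name}; treating as 0",
                    stacklevel=3,
                )
            return 0.0
        return self.frequencies[key]


@dataclass
class RefPanel:
    """Reference-panel derived-allele frequencies across populations."""

    populations: dict[str, PanelPopulation] = field(default_factory=dict)

    def add(self, pop: PanelPopulation) -> None:
        self.populations[pop.name] = pop

    def maf(self, key: str, population: str) -> float:
        """Minor-allele frequency of a variant in one population (absent = 0)."""
        f = self.populations[population].frequency(key)
        return min(f, 1.0 - f)


def _as_matrix(values, n: int, m: int, dtype) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != (n, m):
        raise ValueError(f"expected shape {(n, m)}, got {arr.shape}")
    return arr


@dataclass
class Cohort:
    """Genotyped individuals over a fixed variant list.

    Parameters
    ----------
    variants
        Ordered variant records (columns of the matrices).
    samples
        Sample identifiers (rows).
    genotypes
        ``(n_individuals, n_variants)`` int matrix of ALT-allele copy
        numbers; ``-1`` marks a missing call.
    depth, gq, alt_fraction
        Optional per-genotype metric matrices (float, NaN where absent).
    phased_haplotypes
        Optional ``(n_individuals, 2)`` array of indices into
        ``haplotype_strings`` — the simulation truth retained by the
        haplotype generator.
    truth_frequencies
        Optional variant key → generating derived-allele frequency.
    """

    variants: list[VariantRecord]
    samples: list[str]
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    alt_fraction: np.ndarray | None = None
    phased_haplotypes: np.ndarray | None = None
    haplotype_strings: list[str] | None = None
    truth_frequencies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.variants)
        self.genotypes = _as_matrix(self.genotypes, n, m, np.int8)
        bad = (self.genotypes < -1) | (self.genotypes > 2)
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for attr in ("depth", "gq", "alt_fraction"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, _as_matrix(v, n, m, float))

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, which: int | str | VariantRecord) -> int:
        if isinstance(which, int):
            return which
        if isinstance(which, VariantRecord):
            which = which.key
        for i, v in enumerate(self.variants):
            if which in (v.key, v.rsid, v.name):
                return i
        raise KeyError(f"variant {which!r} not in cohort")

    # -- allele counting ------------------------------------------------
    def derived_dosage(self, j: int) -> np.ndarray:
        """Per-individual derived-allele copy number at column *j* (missing = -1)."""
        g = self.genotypes[:, j].astype(np.int16)
        if not self.variants[j].derived_is_alt:
            called = g >= 0
            g = np.where(called, 2 - g, MISSING)
        return g

    def derived_count(self, j: int) -> int:
        d = self.derived_dosage(j)
        return int(d[d >= 0].sum())

    def called_chromosomes(self, j: int) -> int:
        return 2 * int((self.genotypes[:, j] >= 0).sum())

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts at column *j*, ALT orientation."""
        g = self.genotypes[:, j]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    # -- structural ops -------------------------------------------------
    def subset_samples(self, index: Sequence[int]) -> "Cohort":
        idx = np.asarray(index, dtype=int)

        def take(a):
            return None if a is None else a[idx]

        return Cohort(
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            genotypes=self.genotypes[idx],
            depth=take(self.depth),
            gq=take(self.gq),
            alt_fraction=take(self.alt_fraction),
            phased_haplotypes=take(self.phased_haplotypes),
            haplotype_strings=self.haplotype_strings,
            truth_frequencies=self.truth_frequencies,
        )

    def subset_variants(self, index: Sequence[int]) -> "Cohort":
        idx = np.asarray(index, dtype=int)

        def take(a):
            return None if a is None else a[:, idx]

        return Cohort(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            genotypes=self.genotypes[:, idx],
            depth=take(self.depth),
            gq=take(self.gq),
            alt_fraction=take(self.alt_fraction),
        )

    def copy(self) -> "Cohort":
        return replace(
            self,
            variants=list(self.variants),
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            alt_fraction=None
            if self.alt_fraction is None
            else self.alt_fraction.copy(),
        )

    @staticmethod
    def concatenate(cohorts: Iterable["Cohort"]) -> "Cohort":
        """Stack cohorts sharing an identical variant list along individuals."""
        cohorts = list(cohorts)
        if not cohorts:
            raise ValueError("no cohorts to concatenate")
        keys = [v.key for v in cohorts[0].variants]
        for c in cohorts[1:]:
            if [v.key for v in c.variants] != keys:
                raise ValueError("cohorts do not share a variant list")
        samples = [s for c in cohorts for s in c.samples]
        if len(set(samples)) != len(samples):
            samples = [f"{s}#{i}" for i, s in enumerate(samples)]

        def stack(attr):
            parts = [getattr(c, attr) for c in cohorts]
            if any(p is None for p in parts):
                return None
            return np.concatenate(parts, axis=0)

        return Cohort(
            variants=list(cohorts[0].variants),
            samples=samples,
            genotypes=np.concatenate([c.genotypes for c in cohorts], axis=0),
            depth=stack("depth"),
            gq=stack("gq"),
            alt_fraction=stack("alt_fraction"),
        )
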