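"""EM haplotype-frequency estimation, pairwise LD, and Gabriel-style blocks.

Haplotype frequencies over L ≤ 12 biallelic loci are estimated by the
classic EM algorithm on the multinomial haplotype-pair likelihood under
Hardy-Weinberg: the E-step distributes each phase-ambiguous multilocus
genotype over its compatible haplotype-pair resolutions in proportion to
current frequency products, the M-step re-tallies frequencies.
Initialization is uniform over the compatible haplotypes and every step is
deterministic, so results carry no RNG state.  The log-likelihood is
checked to be non-decreasing at every iteration.

Pairwise LD statistics (D, D′, r², LOD) derive from two-locus EM runs; D′
confidence intervals come from a profile likelihood over |D′| with allele
frequencies held at their sample estimates (seeded bootstrap available as
an alternative), and blocks follow the confidence-interval rules of the
Gabriel haplotype-map construction: a pair is in "strong LD" when its CI
is [≥ 0.6, ≥ 0.98], shows "strong recombination" when the upper bound is
< 0.9, and a run of markers is a block when ≥ 95% of its informative pairs
are in strong LD.  Markers below 5% MAF are excluded from pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .model import MISSING, Cohort, VariantRecord

__all__ = [
    "HaplotypeTable",
    "LDStats",
    "LDBlock",
    "em_haplotype_frequencies",
    "cohort_haplotypes",
    "ld_coefficients",
    "ld_stats",
    "dprime_ci",
    "gabriel_blocks",
    "ld_blocks",
    "haplotype_freq_compare",
]

MAX_LOCI = 12


@dataclass
class HaplotypeTable:
    """EM-estimated haplotype frequencies over an ordered locus list."""

    loci: list[VariantRecord] | None
    frequencies: dict[str, float]
    loglik_trace: list[float]
    iterations: int
    converged: bool
    n_individuals: int
    n_dropped: int = 0
    #: parallel internals: haplotype bitmasks and their frequencies
    hap_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    hap_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def loglikelihood(self) -> float:
        return self.loglik_trace[-1]

    def frequency(self, haplotype: str) -> float:
        return self.frequencies.get(haplotype, 0.0)


def _hap_string(code: int, n_loci: int, loci) -> str:
    bits = [(code >> k) & 1 for k in range(n_loci)]
    if loci is None:
        return "".join(str(b) for b in bits)
    return "".join(
        rec.alt if b else rec.ref for b, rec in zip(bits, loci)
    )


def _compatible_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype-pair resolutions of one multilocus genotype."""
    het = [k for k, g in enumerate(genotype) if g == 1]
    base = sum(1 << k for k, g in enumerate(genotype) if g == 2)
    if not het:
        return [(base, base)]
    pairs = []
    first = het[0]
    rest = het[1:]
    for mask in range(1 << len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for idx, k in enumerate(rest):
            if (mask >> idx) & 1:
                h1 |= 1 << k
            else:
                h2 |= 1 << k
        pairs.append((h1, h2))
    return pairs


def em_haplotype_frequencies(
    genotypes: np.ndarray,
    loci: list[VariantRecord] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeTable:
    """EM haplotype frequencies from an (individuals × loci) genotype matrix.

    Genotype codes are ALT-allele copies {0,1,2}; individuals with a
    missing call at any of the loci are dropped (their count is reported in
    ``n_dropped``).  Convergence is declared when the largest frequency
    change falls below *tol*.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("need a 2-D genotype matrix over >= 2 loci")
    n_loci = g.shape[1]
    if n_loci > MAX_LOCI:
        raise ValueError(f"more than {MAX_LOCI} loci: enumeration bound exceeded")
    for k in range(n_loci):
        if (g[:, k] == MISSING).all():
            raise ValueError(f"locus {k} has no called genotypes")
    complete = (g != MISSING).all(axis=1)
    n_dropped = int((~complete).sum())
    g = g[complete]
    if g.shape[0] == 0:
        raise ValueError("no individual is fully genotyped over the loci")

    classes, counts = np.unique(g, axis=0, return_counts=True)
    pair_sets = [_compatible_pairs(tuple(row)) for row in classes]
    hap_codes = sorted({h for pairs in pair_sets for pair in pairs for h in pair})
    index = {h: i for i, h in enumerate(hap_codes)}
    H = len(hap_codes)
    freqs = np.full(H, 1.0 / H)

    # precompute pair index arrays per genotype class
    pair_idx = [
        (
            np.array([index[a] for a, _ in pairs]),
            np.array([index[b] for _, b in pairs]),
            np.array([2.0 if a != b else 1.0 for a, b in pairs]),
        )
        for pairs in pair_sets
    ]

    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new = np.zeros(H)
        loglik = 0.0
        for cnt, (ia, ib, mult) in zip(counts, pair_idx):
            w = mult * freqs[ia] * freqs[ib]
            norm = w.sum()
            if norm <= 0:
                # all compatible pairs currently at zero frequency; re-seed
                w = mult / mult.sum()
                norm = 1e-300
            else:
                w = w / norm
            np.add.at(new, ia, cnt * w / 2)
            np.add.at(new, ib, cnt * w / 2)
            loglik += cnt * np.log(norm)
        new /= counts.sum()
        if trace and loglik < trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        trace.append(float(loglik))
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            converged = True
            break

    frequencies = {
        _hap_string(h, n_loci, loci): float(f)
        for h, f in zip(hap_codes, freqs)
    }
    return HaplotypeTable(
        loci=list(loci) if loci else None,
        frequencies=frequencies,
        loglik_trace=trace,
        iterations=iterations,
        converged=converged,
        n_individuals=int(counts.sum()),
        n_dropped=n_dropped,
        hap_codes=np.array(hap_codes),
        hap_freqs=freqs,
    )


def cohort_haplotypes(
    cohort: Cohort, loci: list[int | str], **kwargs
) -> HaplotypeTable:
    """Run EM on a subset of cohort variants (by index, key, rsid, or name)."""
    idx = [cohort.variant_index(x) for x in loci]
    return em_haplotype_frequencies(
        cohort.genotypes[:, idx], loci=[cohort.variants[j] for j in idx], **kwargs
    )


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------


def ld_coefficients(f_ab: float, f_a: float, f_b: float):
    """D, D′ and r² from a two-locus haplotype frequency.

    ``f_ab`` is the frequency of the haplotype carrying allele A at locus 1
    and allele B at locus 2; ``f_a``, ``f_b`` the marginal allele
    frequencies.  A monomorphic locus leaves D′ and r² undefined (NaN).
    """
    d = f_ab - f_a * f_b
    if f_a in (0.0, 1.0) or f_b in (0.0, 1.0):
        return d, float("nan"), float("nan")
    if d >= 0:
        d_max = min(f_a * (1 - f_b), f_b * (1 - f_a))
    else:
        d_max = min(f_a * f_b, (1 - f_a) * (1 - f_b))
    dprime = 0.0 if d_max == 0 else d / d_max
    r2 = d**2 / (f_a * (1 - f_a) * f_b * (1 - f_b))
    return d, dprime, r2


@dataclass
class LDStats:
    d: float
    dprime: float
    r2: float
    lod: float
    f_ab: float
    f_a: float
    f_b: float


def _pair_loglik(g2: np.ndarray, hfreq: np.ndarray) -> float:
    """Genotype-data log-likelihood at given 4-haplotype frequencies.

    ``hfreq`` is ordered (ab, Ab, aB, AB) with bit0 = locus 1, bit1 = locus 2
    — i.e. index = a1 + 2·a2 with a=1 the ALT allele.
    """
    classes, counts = np.unique(g2, axis=0, return_counts=True)
    total = 0.0
    for row, cnt in zip(classes, counts):
        pairs = _compatible_pairs(tuple(row))
        lik = 0.0
        for a, b in pairs:
            lik += (2.0 if a != b else 1.0) * hfreq[a] * hfreq[b]
        total += cnt * np.log(max(lik, 1e-300))
    return total


def ld_stats(cohort: Cohort, locus_a: int | str, locus_b: int | str) -> LDStats:
    """Pairwise D, D′, r² and LOD between two cohort variants.

    Haplotype frequencies come from a two-locus EM run; the LOD score is
    the log10 likelihood ratio of those frequencies against linkage
    equilibrium (products of the allele frequencies), both evaluated on the
    genotype data.  Allele "A"/"B" is the ALT allele at each locus.
    """
    ja = cohort.variant_index(locus_a)
    jb = cohort.variant_index(locus_b)
    g2 = cohort.genotypes[:, [ja, jb]]
    g2 = g2[(g2 != MISSING).all(axis=1)]
    table = em_haplotype_frequencies(g2, loci=None, tol=1e-10)
    hfreq = np.zeros(4)
    hfreq[table.hap_codes] = table.hap_freqs
    f_a = hfreq[1] + hfreq[3]
    f_b = hfreq[2] + hfreq[3]
    d, dprime, r2 = ld_coefficients(hfreq[3], f_a, f_b)
    eq = np.array(
        [
            (1 - f_a) * (1 - f_b),
            f_a * (1 - f_b),
            (1 - f_a) * f_b,
            f_a * f_b,
        ]
    )
    lod = (_pair_loglik(g2, hfreq) - _pair_loglik(g2, eq)) / np.log(10)
    return LDStats(d=d, dprime=dprime, r2=r2, lod=float(lod),
                   f_ab=float(hfreq[3]), f_a=float(f_a), f_b=float(f_b))


def _freqs_from_dprime(
    dprime: float, f_a: float, f_b: float, sign: float
) -> np.ndarray:
    if sign >= 0:
        d = dprime * min(f_a * (1 - f_b), f_b * (1 - f_a))
    else:
        d = -dprime * min(f_a * f_b, (1 - f_a) * (1 - f_b))
    h = np.array(
        [
            (1 - f_a) * (1 - f_b) + d,
            f_a * (1 - f_b) - d,
            (1 - f_a) * f_b - d,
            f_a * f_b + d,
        ]
    )
    return np.clip(h, 0.0, None)


def dprime_ci(
    cohort: Cohort,
    locus_a: int | str,
    locus_b: int | str,
    method: str = "profile",
    grid: int = 201,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """(lower, upper) bounds on |D′| for a marker pair.

    ``profile`` (default) evaluates the genotype likelihood on a |D′| grid
    with allele frequencies fixed at their sample estimates and the sign of
    D at its MLE, then takes the 5th/95th percentiles of the normalized
    likelihood.  ``bootstrap`` resamples individuals (seeded) and takes the
    same percentiles of the re-estimated |D′|.
    """
    ja = cohort.variant_index(locus_a)
    jb = cohort.variant_index(locus_b)
    g2 = cohort.genotypes[:, [ja, jb]]
    g2 = g2[(g2 != MISSING).all(axis=1)]
    base = ld_stats(cohort, locus_a, locus_b)
    if not np.isfinite(base.dprime):
        return float("nan"), float("nan")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = []
        n = g2.shape[0]
        for _ in range(n_boot):
            sample = g2[rng.integers(0, n, size=n)]
            t = em_haplotype_frequencies(sample, tol=1e-10)
            hf = np.zeros(4)
            hf[t.hap_codes] = t.hap_freqs
            fa, fb = hf[1] + hf[3], hf[2] + hf[3]
            _, dp, _ = ld_coefficients(hf[3], fa, fb)
            if np.isfinite(dp):
                vals.append(abs(dp))
        if not vals:
            return float("nan"), float("nan")
        return float(np.percentile(vals, 5)), float(np.percentile(vals, 95))
    if method != "profile":
        raise ValueError(f"unknown CI method {method!r}")
    sign = 1.0 if base.d >= 0 else -1.0
    dgrid = np.linspace(0.0, 1.0, grid)
    logl = np.array(
        [
            _pair_loglik(g2, _freqs_from_dprime(dp, base.f_a, base.f_b, sign))
            for dp in dgrid
        ]
    )
    lik = np.exp(logl - logl.max())
    cum = np.cumsum(lik)
    cum /= cum[-1]
    lower = float(dgrid[np.searchsorted(cum, 0.05)])
    upper = float(dgrid[np.searchsorted(cum, 0.95)])
    return lower, upper


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------


@dataclass
class LDBlock:
    """A contiguous run of markers whose informative pairs are in strong LD."""

    start_index: int
    end_index: int  # inclusive
    span_bp: int
    n_markers: int
    strong_fraction: float

    @property
    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


def gabriel_blocks(
    positions,
    ci_lower: np.ndarray,
    ci_upper: np.ndarray,
    maf,
    strong_lower: float = 0.6,
    strong_upper: float = 0.98,
    recomb_upper: float = 0.9,
    min_strong_fraction: float = 0.95,
    maf_exclude: float = 0.05,
) -> list[LDBlock]:
    """Delineate LD blocks from pairwise D′ confidence intervals.

    A pair of markers (both with MAF ≥ *maf_exclude*) shows "strong LD"
    when its CI is [≥ *strong_lower*, ≥ *strong_upper*] and "strong
    recombination" when the upper bound is < *recomb_upper*; other pairs
    are uninformative.  A contiguous run of ≥ 2 markers is a block when at
    least *min_strong_fraction* of its informative pairs are strong-LD
    (and it has at least one); maximal non-overlapping blocks are returned
    left to right.  Positions must be sorted ascending.
    """
    positions = np.asarray(positions)
    if (np.diff(positions) < 0).any():
        raise ValueError("marker positions must be sorted ascending")
    maf = np.asarray(maf, dtype=float)
    m = len(positions)

    def pair_state(i: int, j: int) -> str:
        if maf[i] < maf_exclude or maf[j] < maf_exclude:
            return "excluded"
        lo, hi = ci_lower[i, j], ci_upper[i, j]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            return "excluded"
        if lo >= strong_lower and hi >= strong_upper:
            return "strong"
        if hi < recomb_upper:
            return "recomb"
        return "uninformative"

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            strong = recomb = 0
            for a, b in combinations(range(i, j + 1), 2):
                s = pair_state(a, b)
                if s == "strong":
                    strong += 1
                elif s == "recomb":
                    recomb += 1
            informative = strong + recomb
            if informative == 0:
                continue
            frac = strong / informative
            if frac >= min_strong_fraction:
                candidates.append((i, j, frac))
    # maximal non-overlapping, widest first, ties leftmost
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j, frac in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            LDBlock(
                start_index=i,
                end_index=j,
                span_bp=int(positions[j] - positions[i]),
                n_markers=j - i + 1,
                strong_fraction=frac,
            )
        )
    blocks.sort(key=lambda b: b.start_index)
    return blocks


def ld_blocks(
    cohort: Cohort,
    loci: list[int | str] | None = None,
    ci_method: str = "profile",
    seed: int = 0,
    **gabriel_kwargs,
) -> list[LDBlock]:
    """Gabriel blocks over a cohort's markers (sorted by position)."""
    idx = (
        [cohort.variant_index(x) for x in loci]
        if loci is not None
        else list(range(cohort.n_variants))
    )
    idx.sort(key=lambda j: (cohort.variants[j].chrom, cohort.variants[j].pos))
    m = len(idx)
    positions = [cohort.variants[j].pos for j in idx]
    maf = []
    for j in idx:
        called = cohort.called_chromosomes(j)
        f = cohort.derived_count(j) / called if called else float("nan")
        maf.append(min(f, 1 - f))
    lo = np.full((m, m), np.nan)
    hi = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(a + 1, m):
            lo[a, b], hi[a, b] = dprime_ci(
                cohort, idx[a], idx[b], method=ci_method, seed=seed
            )
    return gabriel_blocks(positions, lo, hi, maf, **gabriel_kwargs)


# ---------------------------------------------------------------------------
# haplotype frequency comparison
# ---------------------------------------------------------------------------


def haplotype_freq_compare(
    count_a: int,
    chrom_a: int,
    freq_b: float | None = None,
    count_b: int | None = None,
    chrom_b: int | None = None,
    mode: str = "one_sample_binomial",
    alternative: str = "greater",
) -> float:
    """Compare a haplotype's frequency between two cohorts.

    ``one_sample_binomial`` treats the comparison frequency *freq_b* as
    fixed and computes the exact binomial tail of ``count_a`` successes in
    ``chrom_a`` chromosomes.  ``two_proportion`` computes the pooled
    two-sample z test on the 2×2 haplotype count table (needs *count_b*,
    *chrom_b*).
    """
    if chrom_a <= 0:
        raise ValueError("zero chromosomes in cohort A")
    if not 0 <= count_a <= chrom_a:
        raise ValueError("count exceeds chromosomes")
    if mode == "one_sample_binomial":
        if freq_b is None:
            if count_b is None or not chrom_b:
                raise ValueError("need freq_b or count_b/chrom_b")
            freq_b = count_b / chrom_b
        return float(
            stats.binomtest(count_a, chrom_a, freq_b, alternative=alternative).pvalue
        )
    if mode != "two_proportion":
        raise ValueError(f"unknown mode {mode!r}")
    if count_b is None or not chrom_b:
        raise ValueError("two_proportion mode needs count_b and chrom_b")
    pa, pb = count_a / chrom_a, count_b / chrom_b
    pooled = (count_a + count_b) / (chrom_a + chrom_b)
    se = np.sqrt(pooled * (1 - pooled) * (1 / chrom_a + 1 / chrom_b))
    if se == 0:
        return 1.0
    z = (pa - pb) / se
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    return float(2 * stats.norm.sf(abs(z)))
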