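"""Published variant catalog for the carnitine acyltransferase gene family.

Data assembled from the published survey of coding variation in these six
genes in a 100-individual Nunavik Inuit cohort, with 1000 Genomes CHB+JPT,
CEU and YRI reference frequencies, a 286-individual 1KGP Asian comparison
cohort, and PolyPhen-2 / MutationTaster deleteriousness scores.  Frequencies
are derived-allele frequencies (derived relative to the reference genome).

Genomic positions and ref/alt alleles of the individual SNVs were not
published; the positions used here are synthetic placements inside each
gene's published region, chosen to preserve the published LD-block spans
(the three common CPT1B missense SNPs span ~8 kb, the CPT2 F352C/V368I pair
~1 kb).  The CPT2 trio alleles reproduce the published T-G-C / T-A-C /
G-A-C / T-G-T haplotype alphabet.
"""

from __future__ import annotations

from .model import GeneModel, PanelPopulation, RefPanel, VariantRecord

#: Gene regions of the longest isoform (1-based inclusive, GRCh37).
GENES: tuple[GeneModel, ...] = (
    GeneModel("CPT1A", "chr11", 68522088, 68609399),
    GeneModel("CPT1B", "chr22", 51007290, 51017096),
    GeneModel("CPT1C", "chr19", 50194365, 50216988),
    GeneModel("CPT2", "chr1", 53662101, 53679869),
    GeneModel("CRAT", "chr9", 131857073, 131873070),
    GeneModel("CROT", "chr7", 86974951, 86989425),
)

#: Reference-panel sample sizes (individuals).
PANEL_SIZES = {"CHB-JPT": 286, "CEU": 178, "YRI": 250}

#: Comparison-cohort size (1KGP Asians, individuals).
N_ASIAN = 286
#: Analysis cohort size after QC exclusions (individuals).
N_INUIT = 100
#: HapMap Asian sample used for the F-statistic contrast (individuals).
N_ASIAN_HAPMAP = 83


def _v(gene, name, chrom, pos, ref, alt, csq, rsid, mt, pp2):
    scores = {}
    if pp2 is not None:
        scores["polyphen2"] = pp2
    if mt is not None:
        scores["mutationtaster"] = mt
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=csq,
        rsid=rsid,
        derived_is_alt=True,
        scores=scores or None,
        name=name,
    )


# (record, inuit_freq, chbjpt_freq, ceu_freq, yri_freq) — the ten missense
# variants observed in the Inuit cohort, with panel frequencies.
INUIT_MISSENSE: tuple[tuple[VariantRecord, float, float, float, float], ...] = (
    (_v("CPT1A", "p.P479L", "chr11", 68551039, "C", "T", "missense",
        "rs80356779", 0.997899, 1.0), 0.955, 0.0, 0.0, 0.0),
    (_v("CPT1B", "p.E531K", "chr22", 51009000, "G", "A", "missense",
        "rs470117", 0.606166, 0.303), 0.305, 0.483, 0.465, 0.088),
    (_v("CPT1B", "p.S427C", "chr22", 51014000, "C", "G", "missense",
        "rs8142477", 0.0, 0.0), 0.675, 0.517, 0.933, 0.258),
    (_v("CPT1B", "p.I66V", "chr22", 51016500, "A", "G", "missense",
        "rs3213445", 0.251908, 0.0), 0.175, 0.358, 0.049, 0.102),
    (_v("CPT1C", "p.T265M", "chr19", 50202000, "C", "T", "missense",
        None, 0.999717, 0.998), 0.005, 0.0, 0.0, 0.0),
    (_v("CPT2", "p.F352C", "chr1", 53676100, "T", "G", "missense",
        "rs2229291", 0.999596, 0.999), 0.280, 0.200, 0.0, 0.013),
    (_v("CPT2", "p.V368I", "chr1", 53676900, "G", "A", "missense",
        "rs1799821", 0.06145, 0.001), 0.525, 0.775, 0.549, 0.252),
    (_v("CPT2", "p.R477W", "chr1", 53678000, "C", "T", "missense",
        None, 0.997459, 1.0), 0.030, 0.0, 0.0, 0.0),
    (_v("CRAT", "p.A603P", "chr9", 131859000, "G", "C", "missense",
        "rs17459086", 0.993409, 0.013), 0.090, 0.070, 0.017, 0.008),
    (_v("CRAT", "p.S78F", "chr9", 131871500, "C", "T", "missense",
        None, 0.999657, 0.906), 0.025, 0.0, 0.0, 0.0),
)

# (record, asian_freq) — rare missense variants of the 1KGP Asian comparison
# cohort (absent from the Inuit cohort); PolyPhen-2 scores as published.
ASIAN_RARE: tuple[tuple[VariantRecord, float], ...] = (
    (_v("CPT1A", "p.I491T", "chr11", 68552000, "T", "C", "missense",
        None, None, 0.0), 0.0035),
    (_v("CPT1B", "p.C659W", "chr22", 51008000, "C", "G", "missense",
        None, None, 1.0), 0.0035),
    (_v("CPT1C", "p.R514Q", "chr19", 50213000, "G", "A", "missense",
        None, None, 1.0), 0.0035),
    (_v("CPT1C", "p.Q97H", "chr19", 50197000, "G", "C", "missense",
        None, None, 0.08), 0.0035),
    (_v("CPT2", "p.S122F", "chr1", 53669000, "C", "T", "missense",
        None, None, 0.018), 0.006),
    (_v("CRAT", "p.V411M", "chr9", 131864000, "G", "A", "missense",
        None, None, 0.803), 0.0035),
)

#: The four major CPT2 haplotypes over (p.F352C, p.V368I, p.R477W) in the
#: Inuit cohort, as published.
CPT2_HAPLOTYPES = {"TGC": 0.45, "TAC": 0.24, "GAC": 0.28, "TGT": 0.03}
CPT2_HAPLOTYPE_LOCI = ("p.F352C", "p.V368I", "p.R477W")

#: Published per-variant FST / FIS between the Inuit cohort and 83 HapMap
#: Asians (13 coding variants, including the three synonymous ones whose
#: allele frequencies were not published).
PUBLISHED_FSTATS: tuple[tuple[str, float, float], ...] = (
    ("p.V616V", 0.0196, -0.04),
    ("p.P479L", 0.9171, -0.0452),
    ("p.F417F", 0.0506, -0.1067),
    ("p.E531K", 0.0414, -0.0273),
    ("p.S427C", 0.0340, 0.0382),
    ("p.I66V", 0.0453, 0.0114),
    ("p.F352C", 0.0298, -0.0925),
    ("p.V368I", 0.0546, 0.0349),
    ("p.R477W", 0.0146, -0.0297),
    ("p.A603P", 0.0045, -0.0227),
    ("p.A575A", 0.0097, -0.0196),
    ("p.S78F", 0.0122, -0.0246),
    ("p.T265M", 0.0024, -0.0048),
)


def all_variants() -> list[VariantRecord]:
    """The union of Inuit-observed and Asian-rare missense variants."""
    return [row[0] for row in INUIT_MISSENSE] + [row[0] for row in ASIAN_RARE]


def inuit_frequencies() -> dict[str, float]:
    """Variant key → derived-allele frequency in the Inuit cohort.

    Variants seen only in the Asian comparison cohort are at 0.
    """
    freqs = {rec.key: f for rec, f, *_ in INUIT_MISSENSE}
    freqs.update({rec.key: 0.0 for rec, _ in ASIAN_RARE})
    return freqs


def asian_frequencies() -> dict[str, float]:
    """Variant key → derived-allele frequency in the 1KGP Asian cohort."""
    freqs = {rec.key: chbjpt for rec, _, chbjpt, _, _ in INUIT_MISSENSE}
    freqs.update({rec.key: f for rec, f in ASIAN_RARE})
    return freqs


def reference_panel() -> RefPanel:
    """The three-population reference panel used for rarity classification.

    The Asian-cohort rare variants carry their 1KGP Asian frequencies in the
    CHB-JPT panel and are absent (frequency 0) from CEU and YRI.
    """
    panel = RefPanel()
    cols = {"CHB-JPT": 2, "CEU": 3, "YRI": 4}
    for pop, col in cols.items():
        freqs = {row[0].key: row[col] for row in INUIT_MISSENSE}
        if pop == "CHB-JPT":
            freqs.update({rec.key: f for rec, f in ASIAN_RARE})
        panel.add(
            PanelPopulation(pop, 2 * PANEL_SIZES[pop], freqs)
        )
    return panel


def gene_models(flank: int = 2000) -> list[GeneModel]:
    return [GeneModel(g.gene, g.chrom, g.start, g.end, flank) for g in GENES]
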