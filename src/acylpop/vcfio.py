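"""Reading and writing the pipeline's on-disk formats.

VCF 4.2 IO goes through :mod:`pysam`.  Variant metadata that the in-memory
model needs but VCF has no standard slot for (gene assignment, consequence
class, derived-allele orientation, deleteriousness scores) travels in INFO
fields ``GENE``, ``CSQCLASS``, ``DERIVED``, ``PP2``, ``MT`` so that a
write → read round trip is lossless.

Tabular side inputs are plain TSV: gene regions (gene, chrom, start, end
[, flank]) and reference-panel frequencies (variant, population, frequency,
chromosomes).  Coordinates are 1-based inclusive everywhere.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import (
    CONSEQUENCE_CLASSES,
    Cohort,
    GeneModel,
    PanelPopulation,
    RefPanel,
    VariantRecord,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "load_gene_models",
    "load_reference_frequencies",
    "write_truth",
]


def assign_gene(
    chrom: str, pos: int, gene_models: list[GeneModel] | None
) -> str | None:
    if not gene_models:
        return None
    for gm in gene_models:
        if gm.contains(chrom, pos):
            return gm.gene
    return None


def _build_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
        header.contigs.add(chrom)
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", 1), ("Type", "String"),
                       ("Description", "Assigned gene symbol")])
    header.add_meta(
        "INFO", items=[("ID", "CSQCLASS"), ("Number", 1), ("Type", "String"),
                       ("Description", "Consequence class")])
    header.add_meta(
        "INFO", items=[("ID", "DERIVED"), ("Number", 1), ("Type", "String"),
                       ("Description", "Derived allele: A(lt) or R(ef)")])
    header.add_meta(
        "INFO", items=[("ID", "PP2"), ("Number", 1), ("Type", "Float"),
                       ("Description", "PolyPhen-2 score")])
    header.add_meta(
        "INFO", items=[("ID", "MT"), ("Number", 1), ("Type", "Float"),
                       ("Description", "MutationTaster score")])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in cohort.samples:
        header.add_sample(s)
    return header


def write_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as uncompressed multi-sample VCF 4.2 (GT:DP:GQ:AD).

    Output is byte-stable for a fixed cohort.  DP/GQ/AD fields are emitted
    only when the corresponding metric matrices are present; AD is
    reconstructed from depth × alternate-read fraction.
    """
    header = _build_header(cohort)
    order = np.lexsort(
        (
            [v.pos for v in cohort.variants],
            [v.chrom for v in cohort.variants],
        )
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            v = cohort.variants[j]
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=v.rsid or v.name,
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.info["CSQCLASS"] = v.consequence
            rec.info["DERIVED"] = "A" if v.derived_is_alt else "R"
            if v.scores:
                if "polyphen2" in v.scores:
                    rec.info["PP2"] = float(v.scores["polyphen2"])
                if "mutationtaster" in v.scores:
                    rec.info["MT"] = float(v.scores["mutationtaster"])
            for i, sample in enumerate(cohort.samples):
                g = int(cohort.genotypes[i, j])
                if g < 0:
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    rec.samples[sample]["GT"] = (1, 1) if g == 2 else (0, g)
                if cohort.depth is not None and math.isfinite(cohort.depth[i, j]):
                    dp = int(cohort.depth[i, j])
                    rec.samples[sample]["DP"] = dp
                    if cohort.alt_fraction is not None and math.isfinite(
                        cohort.alt_fraction[i, j]
                    ):
                        alt = int(round(dp * cohort.alt_fraction[i, j]))
                        rec.samples[sample]["AD"] = (dp - alt, alt)
                if cohort.gq is not None and math.isfinite(cohort.gq[i, j]):
                    rec.samples[sample]["GQ"] = int(cohort.gq[i, j])
            out.write(rec)


def read_vcf(
    path: str | Path, gene_models: list[GeneModel] | None = None
) -> Cohort:
    """Read a multi-sample VCF into a :class:`Cohort`.

    Genotypes become ALT-copy counts {0,1,2} with -1 for missing; DP/GQ and
    the alternate-read fraction (alt AD / total AD) populate the metric
    matrices when present.  Each variant is assigned to the gene whose
    flanked region contains it.  Multi-allelic records are rejected — split
    them upstream (e.g. ``bcftools norm -m-``).
    """
    variants: list[VariantRecord] = []
    geno_cols, dp_cols, gq_cols, af_cols = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at "
                    f"{rec.chrom}:{rec.pos}; split multi-allelics upstream"
                )
            csq = rec.info.get("CSQCLASS", "other")
            if csq not in CONSEQUENCE_CLASSES:
                csq = "other"
            scores = {}
            if "PP2" in rec.info:
                scores["polyphen2"] = float(rec.info["PP2"])
            if "MT" in rec.info:
                scores["mutationtaster"] = float(rec.info["MT"])
            rsid = rec.id if rec.id and rec.id.startswith("rs") else None
            name = None if rsid else rec.id
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=rec.info.get("GENE") or assign_gene(
                        rec.chrom, rec.pos, gene_models),
                    consequence=csq,
                    rsid=rsid,
                    derived_is_alt=rec.info.get("DERIVED", "A") != "R",
                    scores=scores or None,
                    name=name,
                )
            )
            g, dp, gq, af = [], [], [], []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    g.append(-1)
                else:
                    g.append(sum(1 for a in gt if a == 1))
                d = call.get("DP")
                dp.append(float(d) if d is not None else np.nan)
                q = call.get("GQ")
                gq.append(float(q) if q is not None else np.nan)
                ad = call.get("AD")
                if ad is not None and None not in ad and sum(ad) > 0:
                    af.append(ad[1] / sum(ad))
                else:
                    af.append(np.nan)
            geno_cols.append(g)
            dp_cols.append(dp)
            gq_cols.append(gq)
            af_cols.append(af)

    n, m = len(samples), len(variants)
    geno = (
        np.array(geno_cols, dtype=np.int8).T
        if m
        else np.zeros((n, 0), dtype=np.int8)
    )

    def opt(cols):
        if not m:
            return None
        arr = np.array(cols, dtype=float).T
        return arr if np.isfinite(arr).any() else None

    return Cohort(
        variants=variants,
        samples=samples,
        genotypes=geno,
        depth=opt(dp_cols),
        gq=opt(gq_cols),
        alt_fraction=opt(af_cols),
    )


def load_gene_models(path: str | Path, default_flank: int = 2000) -> list[GeneModel]:
    """Load gene regions from TSV columns gene, chrom, start, end [, flank]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene file needs columns {sorted(required)}")
    return [
        GeneModel(
            gene=row.gene,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            flank=int(getattr(row, "flank", default_flank)),
        )
        for row in df.itertuples()
    ]


def load_reference_frequencies(path: str | Path) -> RefPanel:
    """Load a reference panel from TSV (variant, population, frequency, chromosomes).

    One row per variant × population.  Duplicate (variant, population) pairs
    and out-of-range frequencies are errors; variants simply absent from a
    population are treated as frequency 0 (with a warning at lookup time).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "population", "frequency", "chromosomes"}
    if not required.issubset(df.columns):
        raise ValueError(f"refpanel file needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("refpanel file contains no rows")
    dup = df.duplicated(subset=["variant", "population"])
    if dup.any():
        raise ValueError(
            f"duplicate refpanel entries: "
            f"{df.loc[dup, ['variant', 'population']].to_dict('records')}"
        )
    if ((df["frequency"] < 0) | (df["frequency"] > 1)).any():
        raise ValueError("refpanel frequencies must lie in [0, 1]")
    panel = RefPanel()
    for pop, grp in df.groupby("population", sort=False):
        chroms = grp["chromosomes"].unique()
        if len(chroms) != 1:
            raise ValueError(f"inconsistent chromosome counts for {pop}")
        panel.add(
            PanelPopulation(
                name=str(pop),
                chromosomes=int(chroms[0]),
                frequencies=dict(zip(grp["variant"], grp["frequency"])),
            )
        )
    return panel


def write_truth(cohort: Cohort, path: str | Path) -> None:
    """Write the simulation truth (frequencies, haplotype counts) as TSV."""
    rows = []
    if cohort.truth_frequencies:
        for v in cohort.variants:
            rows.append(
                {
                    "record": v.key,
                    "kind": "variant_frequency",
                    "value": cohort.truth_frequencies.get(v.key, np.nan),
                }
            )
    if cohort.phased_haplotypes is not None and cohort.haplotype_strings:
        counts = np.bincount(
            cohort.phased_haplotypes.ravel(),
            minlength=len(cohort.haplotype_strings),
        )
        for h, c in zip(cohort.haplotype_strings, counts):
            rows.append({"record": h, "kind": "haplotype_count", "value": int(c)})
    pd.DataFrame(rows, columns=["record", "kind", "value"]).to_csv(
        path, sep="\t", index=False
    )
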