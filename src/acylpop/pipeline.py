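"""End-to-end pipeline orchestration and bundled fixture generation.

:func:`run_pipeline` executes QC → burden → F-statistics → haplotype/LD →
score comparison on a pair of cohorts and writes one TSV per stage plus a
machine-readable JSON summary and a plain-text log (versions, seeds,
thresholds, genotype-masking counts — no timestamps, so identical config
and seeds give byte-identical outputs).

:func:`make_fixtures` materializes the bundled study scenario: a
100-individual exact-count cohort at the published Nunavik Inuit
derived-allele frequencies, a 286-individual comparison cohort at the
published 1KGP Asian frequencies, the six gene regions, the
three-population reference panel, and the deleteriousness-score table.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, burden, catalog, fstats, haplo, qc, scores, synthdata, vcfio
from .model import Cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_fixtures"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str = ""
    vcf_b: str = ""
    genes: str = ""
    refpanel: str = ""
    out_dir: str = "results"
    min_depth: float = 20.0
    min_gq: float = 10.0
    min_alt_fraction: float = 0.25
    maf: float = 0.01
    n_perm: int = 100_000
    n_rand: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file (# comments allowed)."""
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            caster = {"str": str, "float": float, "int": int}[types[key]]
            values[key] = caster(raw.strip("\"'"))
        return cls(**values)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labeled
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("qc")
def _run_qc(cohort: Cohort, thresholds: qc.QCThresholds, out: Path, tag: str,
            log: list[str]) -> Cohort:
    filtered, masked = qc.filter_genotypes(cohort, thresholds)
    log.append(f"qc[{tag}]: masked {masked} genotypes "
               f"(min_depth={thresholds.min_depth}, min_gq={thresholds.min_gq}, "
               f"min_alt_fraction={thresholds.min_alt_fraction})")
    rows = []
    for j, v in enumerate(filtered.variants):
        freq, k, n = qc.allele_frequency(filtered, j)
        hr, het, ha = filtered.genotype_counts(j)
        rows.append({
            "variant": v.label, "gene": v.gene, "consequence": v.consequence,
            "derived_freq": round(freq, 6), "derived_alleles": k,
            "called_chromosomes": n,
            "hwe_p": round(qc.hwe_exact_test(hr, het, ha), 6),
        })
    pd.DataFrame(rows).to_csv(out / f"qc_{tag}.tsv", sep="\t", index=False)
    return filtered


@_stage("burden")
def _run_burden(a: Cohort, b: Cohort, genes, panel, cfg: PipelineConfig,
                out: Path) -> list[burden.BurdenResult]:
    gene_names = [g.gene for g in genes]
    results = burden.burden_table(
        a, b, gene_names, panel, maf_threshold=cfg.maf,
        n_perm=cfg.n_perm, seed=cfg.seed,
    )
    pd.DataFrame([vars(r) for r in results]).to_csv(
        out / "burden.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return results


@_stage("fstats")
def _run_fstats(a: Cohort, b: Cohort, cfg: PipelineConfig, out: Path) -> dict:
    rows = []
    wc = fstats.cohort_fst(a, b, "weir_cockerham")
    for j, v in enumerate(a.variants):
        row = {"variant": v.label, "gene": v.gene}
        for est in fstats.ESTIMATORS:
            r = (wc[j] if est == "weir_cockerham"
                 else fstats.cohort_fst(a.subset_variants([j]),
                                        b.subset_variants([j]), est)[0])
            row[f"fst_{est}"] = round(r.estimate, 6)
        hr, het, ha = a.genotype_counts(j)
        row["fis"] = round(fstats.fis_per_variant(hr, het, ha), 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "fstat.tsv", sep="\t", index=False)
    summary = {
        "fst_ratio_of_sums": fstats.multilocus_fst(wc, "ratio_of_sums"),
        "fst_arithmetic_mean": fstats.multilocus_fst(wc, "arithmetic_mean"),
    }
    _, p = fstats.fst_randomization_test(
        a, b, n_rand=cfg.n_rand, seed=cfg.seed)
    summary["fst_randomization_p"] = p
    fis_obs, fis_p = fstats.fis_randomization_test(
        a, n_rand=cfg.n_rand, seed=cfg.seed)
    summary["fis_mean"] = fis_obs
    summary["fis_randomization_p"] = fis_p
    return summary


@_stage("haplo")
def _run_haplo(a: Cohort, cfg: PipelineConfig, out: Path) -> dict:
    ld_rows, hap_rows, block_rows = [], [], {}
    for gene in sorted({v.gene for v in a.variants if v.gene}):
        idx = [j for j, v in enumerate(a.variants) if v.gene == gene]
        idx.sort(key=lambda j: a.variants[j].pos)
        polymorphic = [j for j in idx if 0 < a.derived_count(j) < a.called_chromosomes(j)]
        if len(polymorphic) < 2:
            continue
        for x in range(len(polymorphic)):
            for y in range(x + 1, len(polymorphic)):
                s = haplo.ld_stats(a, polymorphic[x], polymorphic[y])
                ld_rows.append({
                    "gene": gene,
                    "locus_a": a.variants[polymorphic[x]].label,
                    "locus_b": a.variants[polymorphic[y]].label,
                    "D": round(s.d, 6), "Dprime": round(s.dprime, 6),
                    "r2": round(s.r2, 6), "LOD": round(s.lod, 4),
                })
        blocks = haplo.ld_blocks(a, loci=polymorphic, seed=cfg.seed)
        block_rows[gene] = [
            {"markers": [a.variants[polymorphic[k]].label for k in b.indices],
             "span_bp": b.span_bp, "strong_fraction": b.strong_fraction}
            for b in blocks
        ]
        if len(polymorphic) <= haplo.MAX_LOCI:
            table = haplo.cohort_haplotypes(a, polymorphic)
            for h, f in sorted(table.frequencies.items()):
                if f > 1e-6:
                    hap_rows.append({
                        "gene": gene, "haplotype": h, "frequency": round(f, 6),
                        "loglik": round(table.loglikelihood, 4),
                        "converged": table.converged,
                    })
    pd.DataFrame(ld_rows).to_csv(out / "ld.tsv", sep="\t", index=False)
    pd.DataFrame(hap_rows).to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    return {"blocks": block_rows}


@_stage("scores")
def _run_scores(a: Cohort, b: Cohort, panel, cfg: PipelineConfig,
                out: Path) -> dict:
    def rare_scores(c: Cohort) -> list[float]:
        vals = []
        for j, v in enumerate(c.variants):
            if (v.consequence == "missense"
                    and burden.classify_rare(v, panel, cfg.maf)
                    and c.derived_count(j) > 0
                    and v.scores and "polyphen2" in v.scores):
                vals.append(v.scores["polyphen2"])
        return vals

    xs, ys = rare_scores(a), rare_scores(b)
    table = scores.score_frequency_table(
        a.variants, {"cohort_a": a, "cohort_b": b})
    table.to_csv(out / "scores.tsv", sep="\t", index=False,
                 float_format="%.6g")
    if xs and ys:
        cmp_ = scores.mann_whitney_exact(xs, ys)
        return {"mann_whitney_u": cmp_.u,
                "mann_whitney_p_one_sided": cmp_.p_one_sided,
                "mann_whitney_p_two_sided": cmp_.p_two_sided,
                "exact": cmp_.exact}
    return {"mann_whitney_u": None}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the JSON summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"acylpop {__version__}",
        f"python {sys.version.split()[0]}",
        f"numpy {np.__version__}",
        f"seed {config.seed}",
    ]
    try:
        genes = vcfio.load_gene_models(config.genes)
        if not genes:
            raise ValueError("empty gene list")
        panel = vcfio.load_reference_frequencies(config.refpanel)
        cohort_a = vcfio.read_vcf(config.vcf, genes)
        cohort_b = vcfio.read_vcf(config.vcf_b, genes)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc

    thresholds = qc.QCThresholds(
        config.min_depth, config.min_alt_fraction, config.min_gq)
    cohort_a = _run_qc(cohort_a, thresholds, out, "a", log)
    cohort_b = _run_qc(cohort_b, thresholds, out, "b", log)

    burden_results = _run_burden(cohort_a, cohort_b, genes, panel, config, out)
    fstat_summary = _run_fstats(cohort_a, cohort_b, config, out)
    haplo_summary = _run_haplo(cohort_a, config, out)
    score_summary = _run_scores(cohort_a, cohort_b, panel, config, out)

    summary = {
        "seed": config.seed,
        "n_individuals": {"a": cohort_a.n_individuals, "b": cohort_b.n_individuals},
        "burden": {
            r.gene: {
                "burden_a": round(r.burden_a, 3),
                "burden_b": round(r.burden_b, 3),
                "ratio": r.ratio,
                "binomial_p": r.binomial_p,
                "permutation_p": r.permutation_p,
                "adjusted_p": r.adjusted_p,
            }
            for r in burden_results
        },
        "fstats": fstat_summary,
        "haplotypes": haplo_summary,
        "scores": score_summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.append("stages completed: qc, burden, fstats, haplo, scores")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return summary


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the bundled study-scenario fixture files; returns their paths.

    Regeneration with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = catalog.all_variants()
    inuit = synthdata.simulate_cohort(synthdata.CohortSpec(
        n_individuals=catalog.N_INUIT,
        variants=[(v, catalog.inuit_frequencies()[v.key]) for v in variants],
        mode="exact_count", seed=seed, sample_prefix="INU",
    ))
    asian = synthdata.simulate_cohort(synthdata.CohortSpec(
        n_individuals=catalog.N_ASIAN,
        variants=[(v, catalog.asian_frequencies()[v.key]) for v in variants],
        mode="exact_count", seed=seed + 1, sample_prefix="ASN",
    ))
    paths = {
        "vcf_a": outdir / "inuit.vcf",
        "vcf_b": outdir / "asian.vcf",
        "truth_a": outdir / "inuit_truth.tsv",
        "truth_b": outdir / "asian_truth.tsv",
        "genes": outdir / "genes.tsv",
        "refpanel": outdir / "refpanel.tsv",
        "scores": outdir / "scores.tsv",
    }
    vcfio.write_vcf(inuit, paths["vcf_a"])
    vcfio.write_vcf(asian, paths["vcf_b"])
    vcfio.write_truth(inuit, paths["truth_a"])
    vcfio.write_truth(asian, paths["truth_b"])
    pd.DataFrame(
        [{"gene": g.gene, "chrom": g.chrom, "start": g.start,
          "end": g.end, "flank": g.flank} for g in catalog.gene_models()]
    ).to_csv(paths["genes"], sep="\t", index=False)
    panel = catalog.reference_panel()
    rows = []
    for pop in sorted(panel.populations):
        p = panel.populations[pop]
        for key in sorted(p.frequencies):
            rows.append({"variant": key, "population": pop,
                         "frequency": p.frequencies[key],
                         "chromosomes": p.chromosomes})
    pd.DataFrame(rows).to_csv(paths["refpanel"], sep="\t", index=False)
    score_rows = []
    for pop, cohort in (("inuit", inuit), ("asian", asian)):
        for j, v in enumerate(cohort.variants):
            if not v.scores:
                continue
            freq, _, _ = qc.allele_frequency(cohort, j)
            score_rows.append({
                "variant": v.label, "gene": v.gene, "population": pop,
                "frequency": round(freq, 6),
                "polyphen2": v.scores.get("polyphen2", ""),
                "mutationtaster": v.scores.get("mutationtaster", ""),
            })
    pd.DataFrame(score_rows).to_csv(paths["scores"], sep="\t", index=False)
    return paths
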