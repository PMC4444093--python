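import numpy as np
import pytest

from acylpop import catalog, synthdata
from acylpop.model import Cohort, VariantRecord


@pytest.fixture(scope="session")
def panel():
    return catalog.reference_panel()


@pytest.fixture(scope="session")
def inuit_cohort():
    """Exact-count cohort at the published Inuit derived-allele frequencies."""
    freqs = catalog.inuit_frequencies()
    return synthdata.simulate_cohort(
        synthdata.CohortSpec(
            n_individuals=catalog.N_INUIT,
            variants=[(v, freqs[v.key]) for v in catalog.all_variants()],
            mode="exact_count",
            seed=101,
            sample_prefix="INU",
        )
    )


@pytest.fixture(scope="session")
def asian_cohort():
    """Exact-count comparison cohort at the published 1KGP Asian frequencies."""
    freqs = catalog.asian_frequencies()
    return synthdata.simulate_cohort(
        synthdata.CohortSpec(
            n_individuals=catalog.N_ASIAN,
            variants=[(v, freqs[v.key]) for v in catalog.all_variants()],
            mode="exact_count",
            seed=202,
            sample_prefix="ASN",
        )
    )


def make_variants(n, chrom="chr1", start=1000, step=100, gene="G1",
                  consequence="other"):
    return [
        VariantRecord(chrom, start + i * step, "A", "G", gene, consequence)
        for i in range(n)
    ]


def tiny_cohort(genotypes, **kwargs):
    """Cohort from a raw genotype matrix with autogenerated variants/samples."""
    g = np.asarray(genotypes, dtype=np.int8)
    return Cohort(
        variants=make_variants(g.shape[1]),
        samples=[f"S{i}" for i in range(g.shape[0])],
        genotypes=g,
        **kwargs,
    )
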