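import numpy as np
import pandas as pd
import pytest

from admixscan.simulate import (
    CohortSimConfig,
    make_snp_table,
    sample_genotypes,
    simulate_cohort,
)

SMALL_CHROMS = {"chr1": 60_000_000, "chr2": 40_000_000, "chrX": 50_000_000}


def small_config(**overrides) -> CohortSimConfig:
    defaults = dict(n_individuals=12, population_size=40, n_generations=3,
                    chrom_lengths=dict(SMALL_CHROMS),
                    n_snps_per_chrom=300, seed=11)
    defaults.update(overrides)
    return CohortSimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_snp_table(small_cohort):
    return make_snp_table(small_cohort.config)


@pytest.fixture(scope="session")
def small_genotypes(small_cohort, small_snp_table):
    return sample_genotypes(small_cohort, small_snp_table)


def segments_frame(rows):
    """Build a segment table from (individual, hap, chrom, start, end, anc)."""
    return pd.DataFrame(
        rows,
        columns=["individual", "haplotype", "chrom", "start", "end", "ancestry"],
    )


def windows_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id"])


def diploid_all(chrom_lengths, individuals, ancestry_by_chrom):
    """Segments covering every chromosome fully with one ancestry per chrom."""
    rows = []
    for ind in individuals:
        for chrom, length in chrom_lengths.items():
            anc = ancestry_by_chrom[chrom]
            for h in (0, 1):
                rows.append((ind, h, chrom, 0, length, anc))
    return segments_frame(rows)


# Decisively sex-separated founding (fathers essentially all European,
# mothers Native-American-majority) with a cohort large enough that the
# 95% CIs resolve the asymmetry; used by the direction/uncertainty checks.
STRONG_BIAS = dict(founder_props_male=(0.05, 0.0, 0.95),
                   founder_props_female=(0.0, 0.85, 0.15),
                   n_individuals=120)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
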