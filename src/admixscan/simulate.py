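"""Forward simulation of a three-way admixed diploid cohort.

The generator emulates a Latin-American-style admixture history: unadmixed
founders whose ancestry is drawn from sex-specific founding proportions
(European-skewed paternal, Native-American-skewed maternal), followed by
discrete generations of random mating with Poisson recombination.  Ancestry
tracts are tracked exactly on autosomes and on X (no recombination in the
male germ line for X; sons receive no paternal X), and genotypes are drawn
from Balding-Nichols diverged ancestral allele frequencies, so the simulated
cohort exercises every downstream stage: tract aggregation, supervised
ancestry estimation, the X-vs-autosome asymmetry statistic, and the
locus-level enrichment scan.

Coordinates are 0-based half-open throughout.  A haplotype is a pair of
arrays ``(ends, anc)``: ``ends`` are cumulative tract end positions (the last
equals the chromosome length) and ``anc`` the ancestry code of each tract
(0=AFR, 1=NAM, 2=EUR).  Tracts tile the chromosome with no gaps and adjacent
tracts never share an ancestry code.

All randomness flows from one master seed through named, order-stable
substreams, so a fixed seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ANCESTRIES, GenotypeMatrix, is_x_chrom

__all__ = [
    "CohortSimConfig", "SimulatedCohort", "Tracts", "TransmissionError",
    "generate_allele_freqs", "recombine_gamete", "simulate_cohort",
    "sample_genotypes", "make_windows", "make_snp_table",
    "expected_cohort_fractions",
]

#: Founding proportions averaging to the Medellin-style cohort means the
#: simulator targets (7.3% AFR, 18.1% NAM, 74.6% EUR) while encoding the
#: strong European-paternal / Native-American-maternal founding asymmetry.
DEFAULT_FOUNDER_MALE = (0.100, 0.050, 0.850)
DEFAULT_FOUNDER_FEMALE = (0.046, 0.312, 0.642)

#: Scaled-down default genome: six autosomes plus X, ~0.87 Gb total.
DEFAULT_CHROM_LENGTHS = {
    "chr1": 200_000_000,
    "chr2": 160_000_000,
    "chr3": 130_000_000,
    "chr4": 110_000_000,
    "chr5": 90_000_000,
    "chr6": 70_000_000,
    "chrX": 155_000_000,
}

_STREAMS = {"freqs": 0, "positions": 1, "pedigree": 2, "genotypes": 3}


class TransmissionError(ValueError):
    """Impossible gamete request (e.g. a paternal X destined for a son)."""


class Tracts(NamedTuple):
    """Ancestry tracts tiling one chromosome copy."""

    ends: np.ndarray  # int64, strictly increasing, last == chrom length
    anc: np.ndarray   # int8 ancestry codes, adjacent entries differ


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],))
    )


@dataclass
class CohortSimConfig:
    """All parameters of the synthetic admixed cohort."""

    n_individuals: int = 60
    population_size: int = 500  # breeding population; the cohort is a sample
    sex_ratio: float = 0.5  # fraction male
    n_generations: int = 6
    founder_props_male: tuple[float, float, float] = DEFAULT_FOUNDER_MALE
    founder_props_female: tuple[float, float, float] = DEFAULT_FOUNDER_FEMALE
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    recomb_rate: float = 1.0  # expected crossovers per 1e8 bp (~1 cM/Mb)
    fst_divergence: float = 0.15
    n_snps_per_chrom: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.population_size < self.n_individuals:
            raise ValueError("population_size must be >= n_individuals")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for props in (self.founder_props_male, self.founder_props_female):
            p = np.asarray(props, dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"founder proportions {props} must be a "
                                 "non-negative 3-vector summing to 1")
        if not all(length > 0 for length in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if not (np.isfinite(self.fst_divergence) and 0 < self.fst_divergence < 1):
            raise ValueError("fst_divergence must be in (0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.n_snps_per_chrom < 1:
            raise ValueError("n_snps_per_chrom must be >= 1")

    @property
    def autosomes(self) -> list[str]:
        return sorted(c for c in self.chrom_lengths if not is_x_chrom(c))

    @property
    def x_chrom(self) -> str | None:
        xs = [c for c in self.chrom_lengths if is_x_chrom(c)]
        return xs[0] if xs else None


@dataclass
class SimIndividual:
    individual_id: str
    sex: str  # "M" or "F"
    # chrom -> list of Tracts; autosomes have 2 entries, X has 2 for females
    # and 1 (the maternal copy, haplotype index 0) for males
    haplotypes: dict[str, list[Tracts]]


@dataclass
class SimulatedCohort:
    """Final-generation individuals plus the tables the pipeline consumes."""

    config: CohortSimConfig
    individuals: list[SimIndividual]
    segments: pd.DataFrame       # io.SEGMENT_COLUMNS
    truth: pd.DataFrame          # per-individual true fractions by compartment
    sexes: dict[str, str]
    # realized ancestry of the entire final breeding generation, pooled with
    # the same length weighting the cohort statistics use (the population
    # parameter a cohort bootstrap estimates)
    population_fractions: dict[str, np.ndarray]

    def population_delta(self, ancestry_idx: int) -> float:
        """Realized population-level (F_X - F_auto) / F_total."""
        pf = self.population_fractions
        return float((pf["F_X"][ancestry_idx] - pf["F_auto"][ancestry_idx])
                     / pf["F_total"][ancestry_idx])


# ---------------------------------------------------------------------------
# allele frequencies (Balding-Nichols)
# ---------------------------------------------------------------------------

def generate_allele_freqs(n_snps: int, fst_divergence: float,
                          seed: int | np.random.Generator) -> np.ndarray:
    """Draw per-SNP ancestral allele frequencies for the three populations.

    A shared base frequency p ~ Uniform(0.05, 0.95) per SNP, then each
    population's frequency independently Beta(p(1-F)/F, (1-p)(1-F)/F)
    (Balding-Nichols), so F controls the divergence of the three populations
    around their shared ancestral frequency (Var = F p (1-p)) and creates the
    population-enriched alleles the downstream estimators rely on.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (np.isfinite(fst_divergence) and 0 < fst_divergence < 1):
        raise ValueError("fst_divergence must be finite and in (0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = rng.uniform(0.05, 0.95, size=n_snps)
    scale = (1.0 - fst_divergence) / fst_divergence
    freqs = np.empty((n_snps, 3))
    for k in range(3):
        freqs[:, k] = rng.beta(base * scale, (1.0 - base) * scale)
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def _slice_tracts(hap: Tracts, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Tracts of ``hap`` restricted to [lo, hi) (ends clipped to hi)."""
    i0 = int(np.searchsorted(hap.ends, lo, side="right"))
    inner = hap.ends[(hap.ends > lo) & (hap.ends < hi)]
    ends = np.append(inner, hi)
    anc = hap.anc[i0:i0 + len(ends)]
    return ends, anc


def _merge_adjacent(ends: np.ndarray, anc: np.ndarray) -> Tracts:
    if len(anc) > 1:
        keep = np.append(anc[:-1] != anc[1:], True)
        ends, anc = ends[keep], anc[keep]
    return Tracts(np.ascontiguousarray(ends, dtype=np.int64),
                  np.ascontiguousarray(anc, dtype=np.int8))


def recombine_gamete(parent_haplotypes: list[Tracts], chrom_length: int,
                     parent_sex: str, rng: np.random.Generator, *,
                     is_x: bool = False, child_sex: str = "F",
                     recomb_rate: float = 1.0) -> Tracts:
    """Produce one gamete from a parent's haplotype pair for one chromosome.

    Crossover count is Poisson(length * recomb_rate / 1e8) with uniform
    breakpoints; the gamete alternates between the two parental copies at
    each breakpoint.  The male X is transmitted intact and only to daughters
    (a paternal X destined for a son raises :class:`TransmissionError`).
    """
    if is_x and parent_sex == "M":
        if child_sex == "M":
            raise TransmissionError("sons receive no paternal X")
        (only,) = parent_haplotypes
        return Tracts(only.ends.copy(), only.anc.copy())
    n_xo = rng.poisson(chrom_length * recomb_rate / 1e8)
    first = int(rng.integers(2))
    if n_xo == 0:
        src = parent_haplotypes[first]
        return Tracts(src.ends.copy(), src.anc.copy())
    breaks = np.unique(rng.integers(1, chrom_length, size=n_xo))
    bounds = np.concatenate(([0], breaks, [chrom_length]))
    pieces_e, pieces_a = [], []
    for i in range(len(bounds) - 1):
        src = parent_haplotypes[(first + i) % 2]
        e, a = _slice_tracts(src, int(bounds[i]), int(bounds[i + 1]))
        pieces_e.append(e)
        pieces_a.append(a)
    return _merge_adjacent(np.concatenate(pieces_e), np.concatenate(pieces_a))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _draw_sexes(n: int, sex_ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Sexes for one generation; both sexes guaranteed present (mating needs
    a father and a mother, and the X pool needs both compartments)."""
    sexes = np.where(rng.random(n) < sex_ratio, "M", "F")
    if (sexes == "M").all():
        sexes[0] = "F"
    elif (sexes == "F").all():
        sexes[0] = "M"
    return sexes


def _founder(sex: str, config: CohortSimConfig,
             rng: np.random.Generator) -> SimIndividual:
    props = (config.founder_props_male if sex == "M"
             else config.founder_props_female)
    haps: dict[str, list[Tracts]] = {}
    for chrom, length in sorted(config.chrom_lengths.items()):
        n_copies = 1 if (is_x_chrom(chrom) and sex == "M") else 2
        haps[chrom] = [
            Tracts(np.array([length], dtype=np.int64),
                   np.array([rng.choice(3, p=props)], dtype=np.int8))
            for _ in range(n_copies)
        ]
    return SimIndividual("", sex, haps)


def _mate(father: SimIndividual, mother: SimIndividual, child_sex: str,
          config: CohortSimConfig, rng: np.random.Generator) -> SimIndividual:
    haps: dict[str, list[Tracts]] = {}
    for chrom, length in sorted(config.chrom_lengths.items()):
        x = is_x_chrom(chrom)
        maternal = recombine_gamete(mother.haplotypes[chrom], length, "F", rng,
                                    is_x=x, child_sex=child_sex,
                                    recomb_rate=config.recomb_rate)
        if x and child_sex == "M":
            haps[chrom] = [maternal]  # hemizygous: haplotype index 0 only
            continue
        paternal = recombine_gamete(father.haplotypes[chrom], length, "M", rng,
                                    is_x=x, child_sex=child_sex,
                                    recomb_rate=config.recomb_rate)
        haps[chrom] = [maternal, paternal]
    return SimIndividual("", child_sex, haps)


def _tract_lengths_by_ancestry(tracts: Tracts) -> np.ndarray:
    starts = np.concatenate(([0], tracts.ends[:-1]))
    lengths = tracts.ends - starts
    return np.bincount(tracts.anc, weights=lengths, minlength=3)


def _individual_fractions(ind: SimIndividual,
                          config: CohortSimConfig) -> dict[str, np.ndarray]:
    auto = np.zeros(3)
    x = np.zeros(3)
    for chrom, haps in ind.haplotypes.items():
        bucket = x if is_x_chrom(chrom) else auto
        for hap in haps:
            bucket += _tract_lengths_by_ancestry(hap)
    out = {"auto_len": auto.sum(), "x_len": x.sum()}
    out["F_auto"] = auto / auto.sum() if auto.sum() else None
    out["F_X"] = x / x.sum() if x.sum() else None
    total = auto + x
    out["F_total"] = total / total.sum()
    return out


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Forward-simulate the admixed cohort described by ``config``.

    Generation 0 founders are unadmixed (each chromosome copy a single
    full-length tract with ancestry drawn per haplotype from the founder
    proportions of the founder's sex).  Each of the ``n_generations`` rounds
    of random mating draws, for every child, a random father and a random
    mother from the previous generation (non-overlapping generations,
    constant ``population_size``).  The returned cohort is a random sample
    of ``n_individuals`` from the final generation — the study design the
    pipeline emulates is a modest cohort drawn from a much larger admixed
    population, so sampling variance (what a bootstrap over individuals
    sees) dominates pedigree drift.  The object carries the cohort's exact
    tracts, the segment table, and per-individual true ancestry fractions
    split into autosomal / X / genome-wide compartments.
    """
    config = config or CohortSimConfig()
    config.validate()
    rng = _stream(config.seed, "pedigree")
    n_pop = config.population_size

    sexes = _draw_sexes(n_pop, config.sex_ratio, rng)
    generation = [_founder(s, config, rng) for s in sexes]
    for _ in range(config.n_generations):
        males = [i for i in generation if i.sex == "M"]
        females = [i for i in generation if i.sex == "F"]
        child_sexes = _draw_sexes(n_pop, config.sex_ratio, rng)
        generation = [
            _mate(males[rng.integers(len(males))],
                  females[rng.integers(len(females))],
                  s, config, rng)
            for s in child_sexes
        ]
    auto_pool = np.zeros(3)
    x_pool = np.zeros(3)
    for ind in generation:
        for chrom, haps in ind.haplotypes.items():
            bucket = x_pool if is_x_chrom(chrom) else auto_pool
            for hap in haps:
                bucket += _tract_lengths_by_ancestry(hap)
    total_pool = auto_pool + x_pool
    population_fractions = {
        "F_auto": auto_pool / auto_pool.sum(),
        "F_X": x_pool / x_pool.sum() if x_pool.sum() else auto_pool * np.nan,
        "F_total": total_pool / total_pool.sum(),
    }

    pick = rng.choice(n_pop, size=config.n_individuals, replace=False)
    generation = [generation[i] for i in np.sort(pick)]

    width = max(3, len(str(config.n_individuals)))
    seg_rows = []
    truth_rows = []
    sexes_out: dict[str, str] = {}
    for i, ind in enumerate(generation, 1):
        ind.individual_id = f"I{i:0{width}d}"
        sexes_out[ind.individual_id] = ind.sex
        for h in (0, 1):  # file order matches the readers' canonical sort
            for chrom in sorted(ind.haplotypes):
                if h >= len(ind.haplotypes[chrom]):
                    continue  # male X has haplotype 0 only
                hap = ind.haplotypes[chrom][h]
                start = 0
                for end, anc in zip(hap.ends, hap.anc):
                    seg_rows.append((ind.individual_id, h, chrom, start,
                                     int(end), ANCESTRIES[anc]))
                    start = int(end)
        fr = _individual_fractions(ind, config)
        row = {"individual": ind.individual_id, "sex": ind.sex}
        for comp in ("total", "auto", "X"):
            vec = fr[f"F_{comp}"]
            for k, a in enumerate(ANCESTRIES):
                row[f"F_{comp}_{a}"] = np.nan if vec is None else vec[k]
        row["auto_len"] = fr["auto_len"]
        row["x_len"] = fr["x_len"]
        truth_rows.append(row)

    segments = pd.DataFrame(
        seg_rows,
        columns=["individual", "haplotype", "chrom", "start", "end", "ancestry"],
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(config, generation, segments, truth, sexes_out,
                           population_fractions)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def make_snp_table(config: CohortSimConfig) -> pd.DataFrame:
    """Draw SNP positions and Balding-Nichols frequencies for every chromosome.

    Returns the allele-frequency table of :mod:`admixscan.io` (``pos`` is
    1-based, VCF convention); positions are distinct and sorted per
    chromosome; REF/ALT are fixed A/G placeholders (the pipeline only uses
    dosages).
    """
    config.validate()
    pos_rng = _stream(config.seed, "positions")
    freq_rng = _stream(config.seed, "freqs")
    frames = []
    for chrom, length in sorted(config.chrom_lengths.items()):
        want = min(config.n_snps_per_chrom, length)
        pos0 = np.unique(pos_rng.integers(0, length, size=want))
        while len(pos0) < want:  # top up collisions (rare)
            extra = pos_rng.integers(0, length, size=want - len(pos0))
            pos0 = np.unique(np.concatenate([pos0, extra]))
        freqs = generate_allele_freqs(want, config.fst_divergence, freq_rng)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos0 + 1, "ref": "A", "alt": "G",
            "freq_AFR": freqs[:, 0], "freq_NAM": freqs[:, 1],
            "freq_EUR": freqs[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)


def sample_genotypes(cohort: SimulatedCohort,
                     snp_table: pd.DataFrame) -> GenotypeMatrix:
    """Draw genotypes for the cohort from the ancestry-conditional frequencies.

    Each haplotype's allele at a SNP is Bernoulli(frequency of the ancestry
    covering that position); the diploid dosage is the allele sum, and males
    are haploid (ploidy 1) on X.
    """
    rng = _stream(cohort.config.seed, "genotypes")
    samples = [ind.individual_id for ind in cohort.individuals]
    n = len(samples)
    dosage_parts, ploidy_parts, variant_parts = [], [], []
    for chrom, grp in snp_table.groupby("chrom", sort=True):
        length = cohort.config.chrom_lengths[chrom]
        pos0 = grp["pos"].to_numpy() - 1
        if (pos0 < 0).any() or (pos0 >= length).any():
            raise ValueError(f"SNP position outside {chrom}")
        freqs = grp[["freq_AFR", "freq_NAM", "freq_EUR"]].to_numpy()
        m = len(grp)
        dos = np.zeros((m, n))
        plo = np.zeros((m, n), dtype=np.int8)
        for j, ind in enumerate(cohort.individuals):
            for hap in ind.haplotypes[chrom]:
                idx = np.searchsorted(hap.ends, pos0, side="right")
                if (idx >= len(hap.anc)).any():
                    raise ValueError(f"SNP not covered by any tract on {chrom}")
                anc = hap.anc[idx]
                dos[:, j] += rng.random(m) < freqs[np.arange(m), anc]
                plo[:, j] += 1
        dosage_parts.append(dos)
        ploidy_parts.append(plo)
        variant_parts.append(grp[["chrom", "pos", "ref", "alt"]])
    variants = pd.concat(variant_parts, ignore_index=True)
    return GenotypeMatrix(samples, variants,
                          np.concatenate(dosage_parts),
                          np.concatenate(ploidy_parts))


# ---------------------------------------------------------------------------
# helpers consumed by the pipeline and tests
# ---------------------------------------------------------------------------

def make_windows(chrom_lengths: dict[str, int], window_size: int = 1_000_000,
                 include_x: bool = False) -> pd.DataFrame:
    """Tile chromosomes with fixed-size locus windows (BED-style table).

    Stands in for recombination-map-derived loci on simulated data; the scan
    only needs sorted, non-overlapping windows.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        if is_x_chrom(chrom) and not include_x:
            continue
        length = chrom_lengths[chrom]
        starts = range(0, length, window_size)
        for s in starts:
            e = min(s + window_size, length)
            rows.append((chrom, s, e, f"{chrom}:{s}-{e}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id"])


def expected_cohort_fractions(config: CohortSimConfig) -> dict[str, np.ndarray]:
    """Generating-process expectations of the cohort ancestry fractions.

    Autosomal expectation is the sex-average of the founding proportions.
    The X expectation follows the standard recursion (a male's X is his
    mother's; a female averages both parents), iterated over the configured
    number of generations, pooled with female X copies double-weighted.
    Used as the known truth in coverage studies of the bootstrap.
    """
    pm = np.asarray(config.founder_props_male, dtype=float)
    pf = np.asarray(config.founder_props_female, dtype=float)
    f_auto = (pm + pf) / 2.0
    m_x, f_x = pm.copy(), pf.copy()
    for _ in range(config.n_generations):
        m_x, f_x = f_x, (m_x + f_x) / 2.0
    s = config.sex_ratio
    f_x_pool = (2 * (1 - s) * f_x + s * m_x) / (2 * (1 - s) + s)
    l_auto = sum(l for c, l in config.chrom_lengths.items() if not is_x_chrom(c))
    l_x = sum(l for c, l in config.chrom_lengths.items() if is_x_chrom(c))
    # expected pooled genome length weights: autosomes count two copies per
    # individual, X counts two per female and one per male
    w_auto = 2 * l_auto
    w_x = l_x * (2 * (1 - s) + s)
    f_total = (w_auto * f_auto + w_x * f_x_pool) / (w_auto + w_x)
    delta = (f_x_pool - f_auto) / f_total
    return {"F_auto": f_auto, "F_X": f_x_pool, "F_total": f_total,
            "delta": delta}
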