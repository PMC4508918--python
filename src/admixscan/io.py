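"""Readers and writers for the flat-file formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention).  The only
1-based format is VCF ``POS``; the two converters below are the single place
where that shift happens.

Formats
-------
- segment TSV: ``individual  haplotype  chrom  start  end  ancestry`` with a
  header line; one row per contiguous local-ancestry tract of one haplotype.
- locus windows / genes: BED3+/BED4 (no header; ``track``/``browser``/``#``
  lines ignored).
- genotypes: VCF with GT; biallelic SNPs only; haploid calls (male X) allowed.
- ancestral allele frequencies: TSV ``chrom pos ref alt freq_AFR freq_NAM
  freq_EUR`` (``pos`` 1-based to match the VCF it annotates).
- chromosome paintings: BED9 with ``itemRgb`` per ancestry, one strand per
  haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical internal ancestry alphabet, in the order (x1, x2, x3) used by the
#: enrichment statistic.  Input label maps translate caller-specific labels
#: (e.g. the YRI/CHB/CEU reference surrogates) at the boundary.
ANCESTRIES = ("AFR", "NAM", "EUR")
ANCESTRY_INDEX = {a: i for i, a in enumerate(ANCESTRIES)}

#: Default label map applied on read: reference-panel surrogate -> ancestry.
SURROGATE_LABELS = {"YRI": "AFR", "CHB": "NAM", "CEU": "EUR"}

#: itemRgb colours for chromosome paintings (colour-blind-safe set1).
PAINT_COLORS = {"AFR": "228,26,28", "NAM": "55,126,184", "EUR": "77,175,74"}

SEGMENT_COLUMNS = ["individual", "haplotype", "chrom", "start", "end", "ancestry"]
FREQ_COLUMNS = ["chrom", "pos", "ref", "alt", "freq_AFR", "freq_NAM", "freq_EUR"]


class FormatError(ValueError):
    """An input file violates its format contract (message names the line)."""


def to_vcf_pos(start0: int) -> int:
    """0-based half-open start -> 1-based VCF POS."""
    return start0 + 1


def from_vcf_pos(pos1: int) -> int:
    """1-based VCF POS -> 0-based coordinate."""
    return pos1 - 1


def is_x_chrom(chrom: str) -> bool:
    return chrom.removeprefix("chr") in ("X", "x")


@dataclass(frozen=True)
class AncestrySegment:
    """One contiguous run of a haplotype assigned to a single ancestry."""

    individual_id: str
    haplotype: int
    chrom: str
    start: int
    end: int
    ancestry: str


@dataclass(frozen=True)
class LocusWindow:
    chrom: str
    start: int
    end: int
    locus_id: str

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a cohort.

    dosage[m, n] is the ALT allele count of sample n at SNP m (NaN = missing);
    ploidy[m, n] is 2, or 1 for hemizygous calls (male X).
    """

    samples: list[str]
    variants: pd.DataFrame  # columns: chrom, pos (1-based), ref, alt
    dosage: np.ndarray
    ploidy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        m, n = self.dosage.shape
        if self.ploidy is None:
            self.ploidy = np.full((m, n), 2, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if len(self.variants) != m or len(self.samples) != n:
            raise ValueError("inconsistent GenotypeMatrix dimensions")
        if self.ploidy.shape != (m, n):
            raise ValueError("ploidy shape does not match dosage")
        with np.errstate(invalid="ignore"):
            if np.any(self.dosage > self.ploidy):
                raise ValueError("dosage exceeds ploidy")

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]


# ---------------------------------------------------------------------------
# segment TSV
# ---------------------------------------------------------------------------

def read_segments(path, label_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a local-ancestry segment TSV into a validated, sorted DataFrame.

    ``label_map`` translates caller-specific ancestry labels into the
    canonical {AFR, NAM, EUR} alphabet; the YRI/CHB/CEU surrogates are always
    accepted.  Coverage gaps between segments are allowed (missing data);
    overlaps on one haplotype are a format error naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "chrom": str})
    if list(df.columns) != SEGMENT_COLUMNS:
        raise FormatError(
            f"{path}: expected header {SEGMENT_COLUMNS}, got {list(df.columns)}"
        )
    # data line i of the file (header = line 1) is df row i-2
    df = df.assign(_line=np.arange(2, len(df) + 2))
    if df.empty:
        return df.drop(columns="_line")
    mapping = dict(SURROGATE_LABELS)
    if label_map:
        mapping.update(label_map)
    df["ancestry"] = df["ancestry"].map(lambda a: mapping.get(a, a))
    bad = ~df["ancestry"].isin(ANCESTRIES)
    if bad.any():
        row = df[bad].iloc[0]
        raise FormatError(f"line {row._line}: unknown ancestry label {row.ancestry!r}")
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise FormatError(f"line {row._line}: start >= end ({row.start} >= {row.end})")
    if (df["haplotype"] < 0).any() or (df["haplotype"] > 1).any():
        raise FormatError("haplotype index must be 0 or 1")
    df = df.sort_values(["individual", "haplotype", "chrom", "start"], kind="stable")
    for _, grp in df.groupby(["individual", "haplotype", "chrom"], sort=False):
        overlap = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
        if overlap.any():
            line = grp["_line"].to_numpy()[1:][overlap][0]
            raise FormatError(f"line {line}: segment overlaps the previous one")
    return df.drop(columns="_line").reset_index(drop=True)


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False, columns=SEGMENT_COLUMNS)


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory segment table by round-tripping the checks."""
    df = segments[SEGMENT_COLUMNS].copy()
    if not df.empty:
        if (df["start"] >= df["end"]).any():
            raise FormatError("segment with start >= end")
        if not df["ancestry"].isin(ANCESTRIES).all():
            raise FormatError("ancestry label outside {AFR, NAM, EUR}")
    return df.sort_values(
        ["individual", "haplotype", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED-like windows and genes
# ---------------------------------------------------------------------------

def _read_bed(path, min_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise FormatError(f"line {lineno}: expected >= {min_cols} columns")
            rows.append((lineno, parts))
    return rows


def read_locus_windows(path) -> pd.DataFrame:
    """Read locus windows (BED3+, optional name column) sorted and validated.

    Windows must be non-overlapping within a chromosome; ``locus_id`` defaults
    to ``chrom:start-end`` when the name column is absent.
    """
    rows = _read_bed(path, 3)
    recs = []
    for lineno, parts in rows:
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise FormatError(f"line {lineno}: start >= end")
        locus_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        recs.append((chrom, start, end, locus_id, lineno))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "locus_id", "_line"])
    df = df.sort_values(["chrom", "start"], kind="stable")
    for _, grp in df.groupby("chrom", sort=False):
        overlap = grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]
        if overlap.any():
            line = grp["_line"].to_numpy()[1:][overlap][0]
            raise FormatError(f"line {line}: window overlaps the previous one")
    return df.drop(columns="_line").reset_index(drop=True)


def write_locus_windows(windows: pd.DataFrame, path) -> None:
    windows.to_csv(
        path, sep="\t", index=False, header=False,
        columns=["chrom", "start", "end", "locus_id"],
    )


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals (BED4: chrom, start, end, name), sorted."""
    rows = _read_bed(path, 4)
    recs = []
    for lineno, parts in rows:
        start, end = int(parts[1]), int(parts[2])
        if start >= end:
            raise FormatError(f"line {lineno}: start >= end")
        recs.append((parts[0], start, end, parts[3]))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False, header=False,
                 columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# allele-frequency TSV
# ---------------------------------------------------------------------------

def read_allele_freqs(path) -> pd.DataFrame:
    """Read the per-SNP ancestral allele-frequency table.

    Columns: chrom, pos (1-based), ref, alt, freq_AFR, freq_NAM, freq_EUR.
    Frequencies outside [0, 1] are a format error naming the line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    if list(df.columns) != FREQ_COLUMNS:
        raise FormatError(f"{path}: expected header {FREQ_COLUMNS}")
    freqs = df[["freq_AFR", "freq_NAM", "freq_EUR"]].to_numpy()
    bad = (freqs < 0) | (freqs > 1) | ~np.isfinite(freqs)
    if bad.any():
        line = int(np.argwhere(bad.any(axis=1))[0][0]) + 2
        raise FormatError(f"line {line}: frequency outside [0, 1]")
    return df


def write_allele_freqs(freqs: pd.DataFrame, path) -> None:
    freqs.to_csv(path, sep="\t", index=False, columns=FREQ_COLUMNS)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNP GT dosages from a VCF.

    Multiallelic records are skipped (count logged); missing calls become
    NaN; haploid calls (male X) get ploidy 1.  A VCF without a GT FORMAT
    field is a format error.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    if "GT" not in [f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "FORMAT"]:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    dosage_rows, ploidy_rows = [], []
    n_multi = 0
    records = vcf(region) if region else vcf
    for rec in records:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        dos = np.empty(len(samples))
        plo = np.empty(len(samples), dtype=np.int8)
        for j, call in enumerate(rec.genotypes):
            alleles = call[:-1]  # last entry is the phasing flag
            plo[j] = len(alleles)
            dos[j] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        dosage_rows.append(dos)
        ploidy_rows.append(plo)
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = np.array(dosage_rows) if dosage_rows else np.empty((0, len(samples)))
    ploidy = (np.array(ploidy_rows, dtype=np.int8) if ploidy_rows
              else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(samples, variants, dosage, ploidy)


def write_genotypes_vcf(gm: GenotypeMatrix, path,
                        chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as VCFv4.2 text (haploid male-X calls as 0/1)."""
    def gt(d: float, p: int) -> str:
        if np.isnan(d):
            return "./." if p == 2 else "."
        d = int(d)
        if p == 1:
            return str(d)
        return ("0/0", "0/1", "1/1")[d]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=admixscan\n")
        seen = dict.fromkeys(gm.variants["chrom"])
        for chrom in seen:
            if chrom_lengths and chrom in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for m, var in enumerate(gm.variants.itertuples(index=False)):
            calls = "\t".join(
                gt(gm.dosage[m, j], int(gm.ploidy[m, j]))
                for j in range(gm.n_samples)
            )
            fh.write(f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# chromosome paintings (BED9)
# ---------------------------------------------------------------------------

def write_painting_bed(segments: pd.DataFrame, path,
                       individual: str | None = None) -> None:
    """Write one individual's ancestry tracts as a BED9 painting track.

    Haplotype 0 is written on strand "+", haplotype 1 on strand "-", so a
    browser can show the two haplotypes as paired tracks; ``itemRgb`` encodes
    the ancestry.
    """
    if individual is None:
        ids = segments["individual"].unique()
        if len(ids) > 1:
            raise ValueError("segments for more than one individual; pass individual=")
        individual = ids[0] if len(ids) else "NA"
    else:
        segments = segments[segments["individual"] == individual]
    with open(path, "w") as fh:
        fh.write(f'track name="{individual}" itemRgb="On"\n')
        for seg in segments.sort_values(["chrom", "haplotype", "start"]).itertuples():
            strand = "+" if seg.haplotype == 0 else "-"
            rgb = PAINT_COLORS[seg.ancestry]
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.ancestry}\t0\t"
                     f"{strand}\t{seg.start}\t{seg.end}\t{rgb}\n")


def read_painting_bed(path) -> pd.DataFrame:
    """Read a painting BED9 back into a segment table (for round-trips)."""
    individual = "NA"
    recs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                if 'name="' in line:
                    individual = line.split('name="')[1].split('"')[0]
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError("painting BED must have 9 columns")
            recs.append((individual, 0 if parts[5] == "+" else 1, parts[0],
                         int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(recs, columns=SEGMENT_COLUMNS)
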