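"""Pipeline orchestration: simulate -> global ancestry -> sex bias -> scan.

Every run writes a JSON manifest (parameters, seed, input checksums, output
checksums, stage status) into the output directory — also on failure, with
the failing stage recorded — so any result file can be traced to the exact
configuration that produced it.  All outputs are flat text (TSV/BED/VCF).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ancestry, io, scan as scan_mod, sexbias
from . import simulate as sim_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, stage toggles and statistical defaults for one run."""

    out_dir: str = "admixscan_out"
    # inputs (ignored when simulate=True, which generates them)
    segments_path: str | None = None
    vcf_path: str | None = None
    windows_path: str | None = None
    freqs_path: str | None = None
    genes_path: str | None = None
    sexes_path: str | None = None   # TSV: individual<TAB>sex
    # stages
    simulate: bool = False
    run_global: bool = True
    run_sexbias: bool = True
    run_scan: bool = True
    run_report: bool = True
    # statistical defaults
    alpha_p: float = 1e-9
    n_boot: int = 1000
    score: str = "exact_tail"
    window_size: int = 1_000_000
    f_total_includes_x: bool = True
    seed: int = 0
    sim: sim_mod.CohortSimConfig = field(default_factory=sim_mod.CohortSimConfig)

    def validate_inputs(self) -> None:
        """Fail before any compute if a required input path is missing."""
        if self.simulate:
            return
        required = {"segments_path": self.segments_path}
        if self.run_global and self.vcf_path is not None:
            required["vcf_path"] = self.vcf_path
            required["freqs_path"] = self.freqs_path
        if self.run_scan:
            required["windows_path"] = self.windows_path
        for name, p in required.items():
            if p is None:
                raise FileNotFoundError(f"config requires {name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name, p in (("genes_path", self.genes_path),
                        ("sexes_path", self.sexes_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage error aborts the run; the manifest (with the failing stage and
    message) is still written before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
        },
        "sim_parameters": dataclasses.asdict(config.sim),
        "stages": [],
        "inputs": {},
        "outputs": {},
        "status": "running",
    }

    def finish(path: Path) -> None:
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        config.validate_inputs()
        _run_stages(config, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        finish(out)
        raise
    finish(out)
    return manifest


def _record_output(manifest: dict, path: Path) -> None:
    manifest["outputs"][path.name] = _sha256(path)


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    rng_seed = config.seed

    # ---- simulate -------------------------------------------------------
    if config.simulate:
        manifest["stages"].append("simulate")
        sim_cfg = dataclasses.replace(config.sim, seed=rng_seed)
        cohort = sim_mod.simulate_cohort(sim_cfg)
        snp_table = sim_mod.make_snp_table(sim_cfg)
        gm = sim_mod.sample_genotypes(cohort, snp_table)
        windows = sim_mod.make_windows(sim_cfg.chrom_lengths,
                                        config.window_size)
        segments = cohort.segments
        sexes = cohort.sexes

        io.write_segments(segments, out / "segments.tsv")
        io.write_allele_freqs(snp_table, out / "allele_freqs.tsv")
        io.write_genotypes_vcf(gm, out / "genotypes.vcf",
                               sim_cfg.chrom_lengths)
        io.write_locus_windows(windows, out / "windows.bed")
        cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(sexes.items(), columns=["individual", "sex"]).to_csv(
            out / "sexes.tsv", sep="\t", index=False)
        for name in ("segments.tsv", "allele_freqs.tsv", "genotypes.vcf",
                     "windows.bed", "truth.tsv", "sexes.tsv"):
            _record_output(manifest, out / name)
        freqs = snp_table
    else:
        for name, p in (("segments", config.segments_path),
                        ("windows", config.windows_path),
                        ("vcf", config.vcf_path),
                        ("freqs", config.freqs_path),
                        ("genes", config.genes_path),
                        ("sexes", config.sexes_path)):
            if p:
                manifest["inputs"][name] = _sha256(Path(p))
        segments = io.read_segments(config.segments_path)
        windows = (io.read_locus_windows(config.windows_path)
                   if config.windows_path else None)
        gm = (io.read_genotypes_vcf(config.vcf_path)
              if config.vcf_path else None)
        freqs = (io.read_allele_freqs(config.freqs_path)
                 if config.freqs_path else None)
        sexes = None
        if config.sexes_path:
            sx = pd.read_csv(config.sexes_path, sep="\t",
                             dtype={"individual": str})
            sexes = dict(zip(sx["individual"], sx["sex"]))

    genes = io.read_gene_bed(config.genes_path) if config.genes_path else None

    # ---- global ancestry ------------------------------------------------
    records = None
    if config.run_global:
        manifest["stages"].append("global")
        records = ancestry.fractions_from_tracts(
            segments, sexes,
            include_x_in_total=config.f_total_includes_x)
        ancestry.records_to_frame(records).to_csv(
            out / "global_ancestry.tsv", sep="\t", index=False)
        _record_output(manifest, out / "global_ancestry.tsv")
        if gm is not None and gm.n_snps > 0:
            dist = ancestry.allele_sharing_distance(gm)
            dist.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
            proj = ancestry.pca_project(dist, n_components=min(5, len(dist.samples)))
            proj.to_frame().to_csv(out / "pca_coords.tsv", sep="\t")
            pd.DataFrame({
                "component": [f"PC{i+1}" for i in
                              range(len(proj.explained_variance_ratio))],
                "explained_variance_ratio": proj.explained_variance_ratio,
            }).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
            for name in ("distance_matrix.tsv", "pca_coords.tsv",
                         "pca_variance.tsv"):
                _record_output(manifest, out / name)
            if freqs is not None:
                em = ancestry.SupervisedAdmixtureEM().fit(gm, freqs)
                em.proportions_.rename_axis("individual").to_csv(
                    out / "admixture_em.tsv", sep="\t")
                _record_output(manifest, out / "admixture_em.tsv")

    # ---- sex asymmetry --------------------------------------------------
    asym = None
    if config.run_sexbias:
        manifest["stages"].append("sexbias")
        if records is None:
            records = ancestry.fractions_from_tracts(
            segments, sexes,
            include_x_in_total=config.f_total_includes_x)
        asym = sexbias.asymmetry_table(records, n_boot=config.n_boot,
                                       seed=config.seed)
        asym.to_csv(out / "sex_asymmetry.tsv", sep="\t", index=False)
        _record_output(manifest, out / "sex_asymmetry.tsv")

    # ---- enrichment scan ------------------------------------------------
    results = None
    if config.run_scan:
        manifest["stages"].append("scan")
        if windows is None:
            raise ValueError("scan stage needs locus windows")
        scanner = scan_mod.EnrichmentScan(alpha_p=config.alpha_p,
                                          score=config.score)
        scanner.fit(segments, windows)
        results = scanner.results_
        results.to_csv(out / "enrichment_results.tsv", sep="\t", index=False)
        merged = scan_mod.merge_significant_segments(results)
        if genes is not None and not merged.empty:
            merged = scan_mod.annotate_genes(merged, genes)
        merged.to_csv(out / "enriched_segments.tsv", sep="\t", index=False)
        grid = scan_mod.combination_frequency_grid(scanner.counts_)
        grid.to_csv(out / "combination_grid.tsv", sep="\t")
        make_manhattan_table(results, config.score).to_csv(
            out / "manhattan.tsv", sep="\t", index=False)
        for name in ("enrichment_results.tsv", "enriched_segments.tsv",
                     "combination_grid.tsv", "manhattan.tsv"):
            _record_output(manifest, out / name)

    # ---- report ---------------------------------------------------------
    if config.run_report:
        manifest["stages"].append("report")
        if records is None:
            records = ancestry.fractions_from_tracts(
            segments, sexes,
            include_x_in_total=config.f_total_includes_x)
        summary = make_summary(records, asym, results)
        (out / "summary.txt").write_text(summary)
        _record_output(manifest, out / "summary.txt")
        first = segments["individual"].iloc[0] if len(segments) else None
        if first is not None:
            io.write_painting_bed(segments, out / f"painting_{first}.bed",
                                  individual=first)
            _record_output(manifest, out / f"painting_{first}.bed")


def make_manhattan_table(results: pd.DataFrame,
                         score: str = "exact_tail") -> pd.DataFrame:
    """Genome-ordered table of -log10 per-locus scores for plotting."""
    col = "pmf" if score == "pmf" else "tail_p"
    def chrom_key(c: str):
        base = c.removeprefix("chr")
        return (0, int(base)) if base.isdigit() else (1, base)
    res = results.copy()
    res["_key"] = res["chrom"].map(chrom_key)
    res = res.sort_values(["_key", "start"], kind="stable")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(res[col].to_numpy())
    out = pd.DataFrame({
        "chrom": res["chrom"].to_numpy(),
        "midpoint": (res["start"].to_numpy() + res["end"].to_numpy()) // 2,
        "neg_log10_score": neglog,
    })
    return out.reset_index(drop=True)


def make_summary(records, asym: pd.DataFrame | None,
                 results: pd.DataFrame | None) -> str:
    """Human-readable run summary (per-ancestry mean/range, scan counts)."""
    from .io import ANCESTRIES

    frame = ancestry.records_to_frame(records)
    lines = ["admixscan run summary", "=====================", "",
             f"individuals: {len(frame)}", "", "global ancestry (genome-wide):"]
    for a in ANCESTRIES:
        vals = frame[f"F_total_{a}"] * 100
        lines.append(f"  {a}: average = {vals.mean():.1f}%, "
                     f"range = {vals.min():.1f}%-{vals.max():.1f}%")
    if asym is not None:
        lines += ["", "sex-biased admixture (delta = (F_X - F_auto)/F_total):"]
        for row in asym.itertuples():
            lines.append(
                f"  {row.ancestry}: delta = {row.delta:+.3f} "
                f"[{row.ci_low:+.3f}, {row.ci_high:+.3f}] "
                f"(P_nonzero = {row.p_nonzero:.3g}, n_boot = {row.n_boot})")
    if results is not None:
        n_sig = int(results["significant"].sum())
        lines += ["", f"enrichment scan: {len(results)} loci scanned, "
                      f"{n_sig} significant"]
    return "\n".join(lines) + "\n"
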