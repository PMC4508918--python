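"""Genome-wide ancestry-enrichment scan.

At each recombination-defined locus window the cohort contributes up to
2N chromosomes (one per haplotype; males one on X), each carrying one of
three ancestries.  Under neutral assortment the per-locus count vector
(x1, x2, x3) = (AFR, NAM, EUR) is trinomial with the population-average
ancestry proportions, so a locus whose combination is improbable under that
trinomial is ancestry-enriched (or depleted).

Two per-locus scores are computed side by side:

- ``pmf``: the trinomial point probability of the observed combination —
  the score the original analysis plots and thresholds; and
- ``exact_tail``: the exact multinomial test P (sum of the probabilities of
  all outcomes no more probable than the observed one), which is a
  calibrated P-value and the default basis for significance calls and
  Benjamini-Hochberg q-values.

Log-fold enrichment per ancestry is log2(observed / expected) counts; merged
runs of significant loci with a shared enriched ancestry form reportable
segments, intersected with gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import ANCESTRIES, is_x_chrom

__all__ = [
    "ExpectedProportions", "EnrichmentScan", "population_average_proportions",
    "locus_counts", "trinomial_pmf", "trinomial_logpmf",
    "exact_multinomial_tail", "MultinomialTailTable", "bh_qvalues",
    "logfold_enrichment", "scan_genome", "combination_frequency_grid",
    "merge_significant_segments", "annotate_genes",
]

_COUNT_COLS = ["x_AFR", "x_NAM", "x_EUR"]


class ExpectedProportions(NamedTuple):
    p1: float  # AFR
    p2: float  # NAM
    p3: float  # EUR

    @property
    def vector(self) -> np.ndarray:
        return np.array(self)


def population_average_proportions(counts: pd.DataFrame) -> ExpectedProportions:
    """Pooled ancestry proportions over all loci: p_k = sum x_k / sum n."""
    totals = counts[_COUNT_COLS].to_numpy(dtype=float).sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no observed chromosomes in any locus")
    return ExpectedProportions(*(totals / grand))


# ---------------------------------------------------------------------------
# per-locus counts
# ---------------------------------------------------------------------------

def locus_counts(segments: pd.DataFrame, windows: pd.DataFrame,
                 chrom_class: str = "autosome") -> pd.DataFrame:
    """Count chromosomes per ancestry at each locus window.

    Each haplotype contributes the ancestry of the segment covering the
    window midpoint (half-open intervals, so a boundary exactly at the
    midpoint assigns the segment starting there); haplotypes with no
    covering segment reduce that locus's n.  ``chrom_class`` selects
    "autosome", "X", or "all" windows.
    """
    if chrom_class not in ("autosome", "X", "all"):
        raise ValueError("chrom_class must be autosome, X or all")
    w = windows.copy()
    wx = w["chrom"].map(is_x_chrom)
    if chrom_class == "autosome":
        w = w[~wx]
    elif chrom_class == "X":
        w = w[wx]
    w = w.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    counts = np.zeros((len(w), 3), dtype=np.int64)
    anc_codes = segments["ancestry"].map(
        {a: i for i, a in enumerate(ANCESTRIES)}).to_numpy()
    seg = segments.assign(_anc=anc_codes)
    for chrom, wgrp in w.groupby("chrom", sort=False):
        mids = ((wgrp["start"].to_numpy() + wgrp["end"].to_numpy()) // 2)
        rows = wgrp.index.to_numpy()
        chrom_segs = seg[seg["chrom"] == chrom]
        for _, hap in chrom_segs.groupby(["individual", "haplotype"], sort=False):
            starts = hap["start"].to_numpy()
            ends = hap["end"].to_numpy()
            anc = hap["_anc"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends, anc = starts[order], ends[order], anc[order]
            i = np.searchsorted(starts, mids, side="right") - 1
            covered = (i >= 0) & (mids < ends[np.clip(i, 0, None)])
            np.add.at(counts, (rows[covered], anc[i[covered]]), 1)
    out = w[["locus_id", "chrom", "start", "end"]].copy()
    out[_COUNT_COLS] = counts
    out["n"] = counts.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# trinomial probability and exact test
# ---------------------------------------------------------------------------

def trinomial_logpmf(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Natural-log trinomial pmf, log-gamma based, vectorised over rows of x.

    A category with p_k = 0 and x_k > 0 yields -inf (pmf exactly 0).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = np.asarray(p, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    n = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        terms = np.where(x > 0, x * logp, 0.0)  # 0*log(0) := 0
    out = gammaln(n + 1) - gammaln(x + 1).sum(axis=1) + terms.sum(axis=1)
    out = np.where(np.isnan(out), -np.inf, out)
    return out


def trinomial_pmf(x1: int, x2: int, x3: int,
                  p: ExpectedProportions | np.ndarray) -> float:
    """P(x1, x2, x3) = n!/(x1! x2! x3!) p1^x1 p2^x2 p3^x3."""
    vec = p.vector if isinstance(p, ExpectedProportions) else np.asarray(p)
    return float(np.exp(trinomial_logpmf([[x1, x2, x3]], vec)[0]))


class MultinomialTailTable:
    """Exact multinomial test P-values for all outcomes at a fixed (n, p).

    Enumerates the (n+1)(n+2)/2 compositions once, orders them by pmf, and
    serves the point-probability-ordered tail P for any observed triple.
    Shared across loci with the same n during a scan.
    """

    # log-space tie tolerance: outcomes whose pmf is within a relative
    # 1e-9 of the observed pmf count as ties (included in the tail)
    _LOG_TIE = 1e-9

    def __init__(self, n: int, p: ExpectedProportions | np.ndarray):
        if n > 10_000:
            raise ValueError("exact enumeration limited to n <= 10000")
        self.n = int(n)
        self.p = p.vector if isinstance(p, ExpectedProportions) else np.asarray(p)
        y1, y2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (y1 + y2) <= n
        y = np.column_stack([y1[keep], y2[keep], n - y1[keep] - y2[keep]])
        lp = trinomial_logpmf(y, self.p)
        order = np.argsort(lp, kind="stable")
        self._sorted_lp = lp[order]
        self._cum = np.cumsum(np.exp(self._sorted_lp))
        self._index = {(int(a), int(b)): i for i, (a, b) in
                       enumerate(zip(y1[keep][order], y2[keep][order]))}

    def tail(self, x1: int, x2: int, x3: int) -> float:
        if x1 + x2 + x3 != self.n:
            raise ValueError("counts do not sum to the table's n")
        i = self._index[(int(x1), int(x2))]
        lp = self._sorted_lp[i]
        j = int(np.searchsorted(self._sorted_lp, lp + self._LOG_TIE,
                                side="right"))
        return float(min(self._cum[j - 1], 1.0))


def exact_multinomial_tail(x1: int, x2: int, x3: int,
                           p: ExpectedProportions | np.ndarray) -> float:
    """Exact multinomial test: P = sum of pmf over outcomes with
    pmf(y) <= pmf(x) (point-probability ordering).  Equals 1 at the mode and
    is never smaller than the observed pmf."""
    return MultinomialTailTable(x1 + x2 + x3, p).tail(x1, x2, x3)


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order of input preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def logfold_enrichment(counts: np.ndarray, p: ExpectedProportions | np.ndarray,
                       n: int | None = None) -> np.ndarray:
    """log2(observed / expected) counts per ancestry.

    Zero observed counts give -inf (a true depletion sentinel; tabular
    output keeps the -inf, plotting floors it).
    """
    x = np.asarray(counts, dtype=float)
    vec = p.vector if isinstance(p, ExpectedProportions) else np.asarray(p)
    if n is None:
        n = x.sum(axis=-1, keepdims=True)
    expected = n * vec
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(x / expected)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

class EnrichmentScan(BaseEstimator):
    """Per-locus trinomial ancestry-enrichment scan with BH FDR control.

    Parameters
    ----------
    alpha_p : float
        Significance threshold applied to the chosen score (the original
        analysis uses P < 1e-9 on the trinomial probability).
    score : {"exact_tail", "pmf"}
        Which per-locus score feeds the threshold and the BH q-values.
        "pmf" replicates the original analysis' use of the point
        probability; "exact_tail" (default) is the calibrated exact test.
    expected : ExpectedProportions or None
        Fixed expected proportions; None (default) re-estimates them from
        the pooled counts of the scanned loci themselves.
    chrom_class : {"autosome", "X", "all"}
        Which windows to scan; autosomes only by default (X counts have a
        different denominator and are opt-in).

    Attributes (after fit): ``counts_``, ``expected_proportions_``,
    ``results_`` (one row per locus with n > 0), ``n_excluded_``.
    """

    def __init__(self, alpha_p: float = 1e-9, score: str = "exact_tail",
                 expected: ExpectedProportions | None = None,
                 chrom_class: str = "autosome"):
        self.alpha_p = alpha_p
        self.score = score
        self.expected = expected
        self.chrom_class = chrom_class

    def fit(self, segments: pd.DataFrame,
            windows: pd.DataFrame) -> "EnrichmentScan":
        counts = locus_counts(segments, windows, chrom_class=self.chrom_class)
        return self.fit_counts(counts)

    def fit_counts(self, counts: pd.DataFrame) -> "EnrichmentScan":
        """Run the scan on a precomputed per-locus count table."""
        if self.score not in ("exact_tail", "pmf"):
            raise ValueError("score must be 'exact_tail' or 'pmf'")
        self.counts_ = counts
        observed = counts[counts["n"] > 0].reset_index(drop=True)
        self.n_excluded_ = int((counts["n"] == 0).sum())
        if observed.empty:
            raise ValueError("no locus has observed chromosomes")
        p = self.expected or population_average_proportions(observed)
        self.expected_proportions_ = p

        x = observed[_COUNT_COLS].to_numpy()
        pmf = np.exp(trinomial_logpmf(x, p.vector))
        tails = np.empty(len(observed))
        tables: dict[int, MultinomialTailTable] = {}
        for n_val in np.unique(observed["n"].to_numpy()):
            tables[int(n_val)] = MultinomialTailTable(int(n_val), p)
        for i, (row, n_val) in enumerate(zip(x, observed["n"].to_numpy())):
            tails[i] = tables[int(n_val)].tail(*row)

        score_vals = pmf if self.score == "pmf" else tails
        q = bh_qvalues(np.minimum(score_vals, 1.0))
        lf = logfold_enrichment(x, p)

        res = observed.copy()
        res[["p_AFR", "p_NAM", "p_EUR"]] = np.broadcast_to(p.vector, x.shape)
        res["pmf"] = pmf
        res["tail_p"] = tails
        res["q_value"] = q
        res[["lf_AFR", "lf_NAM", "lf_EUR"]] = lf
        res["significant"] = score_vals < self.alpha_p
        enriched, depleted = [], []
        for i in range(len(res)):
            # -inf (zero observed) is the strongest possible depletion
            kmax = int(np.argmax(np.where(np.isfinite(lf[i]), lf[i], -np.inf)))
            kmin = int(np.argmin(lf[i]))
            if res["significant"].iat[i]:
                enriched.append(ANCESTRIES[kmax] if lf[i][kmax] > 0 else None)
                depleted.append(ANCESTRIES[kmin] if lf[i][kmin] < 0 else None)
            else:
                enriched.append(None)
                depleted.append(None)
        res["enriched"] = enriched
        res["depleted"] = depleted
        self.results_ = res
        return self


def scan_genome(segments: pd.DataFrame, windows: pd.DataFrame,
                alpha_p: float = 1e-9, score: str = "exact_tail",
                chrom_class: str = "autosome") -> pd.DataFrame:
    """Functional wrapper over :class:`EnrichmentScan`; returns ``results_``."""
    return EnrichmentScan(alpha_p=alpha_p, score=score,
                          chrom_class=chrom_class).fit(segments, windows).results_


# ---------------------------------------------------------------------------
# summaries and reports
# ---------------------------------------------------------------------------

def combination_frequency_grid(counts: pd.DataFrame,
                               n_bins: int | None = None) -> pd.DataFrame:
    """Population frequency of each (x_AFR, x_NAM) combination over loci.

    The third component is determined by the first two, so the grid is
    two-dimensional.  When loci share one n the grid is exact over counts;
    with heterogeneous n, proportions x/n are binned on a fixed grid with
    ``n_bins`` cells per axis (default: max n + 1).  Entries sum to 1.
    """
    obs = counts[counts["n"] > 0]
    if obs.empty:
        raise ValueError("no observed loci")
    ns = obs["n"].to_numpy()
    x1 = obs["x_AFR"].to_numpy()
    x2 = obs["x_NAM"].to_numpy()
    if len(np.unique(ns)) == 1 and n_bins is None:
        n = int(ns[0])
        grid = np.zeros((n + 1, n + 1))
        np.add.at(grid, (x1, x2), 1.0)
        grid /= grid.sum()
        axis = np.arange(n + 1)
        return pd.DataFrame(grid, index=pd.Index(axis, name="x_AFR"),
                            columns=pd.Index(axis, name="x_NAM"))
    nb = n_bins or int(ns.max()) + 1
    edges = np.linspace(0.0, 1.0, nb + 1)
    i1 = np.clip(np.searchsorted(edges, x1 / ns, side="right") - 1, 0, nb - 1)
    i2 = np.clip(np.searchsorted(edges, x2 / ns, side="right") - 1, 0, nb - 1)
    grid = np.zeros((nb, nb))
    np.add.at(grid, (i1, i2), 1.0)
    grid /= grid.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(grid, index=pd.Index(centers, name="frac_AFR"),
                        columns=pd.Index(centers, name="frac_NAM"))


def merge_significant_segments(results: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of adjacent significant loci sharing an enriched ancestry.

    Adjacent means consecutive scanned loci on the same chromosome (in
    genome order); each merged segment carries the minimum tail P and pmf of
    its member loci.
    """
    res = results.sort_values(["chrom", "start"], kind="stable")
    rows = []
    current = None
    prev_key = None
    for row in res.itertuples():
        key = (row.chrom,)
        sig = bool(row.significant) and row.enriched is not None
        if sig and current is not None and prev_key == key \
                and current["enriched"] == row.enriched:
            current["end"] = row.end
            current["min_tail_p"] = min(current["min_tail_p"], row.tail_p)
            current["min_pmf"] = min(current["min_pmf"], row.pmf)
            current["n_loci"] += 1
        else:
            if current is not None:
                rows.append(current)
            current = ({"chrom": row.chrom, "start": row.start, "end": row.end,
                        "enriched": row.enriched, "min_tail_p": row.tail_p,
                        "min_pmf": row.pmf, "n_loci": 1}
                       if sig else None)
        prev_key = key if sig else None
    if current is not None:
        rows.append(current)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "enriched",
                                       "min_tail_p", "min_pmf", "n_loci"])


def annotate_genes(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach genes overlapping each merged segment by >= 1 bp (half-open).

    A gene merely abutting a segment end does not overlap.  Gene names are
    reported sorted by start coordinate, comma-joined.
    """
    out = segments.copy()
    names = []
    for seg in segments.itertuples():
        hit = genes[(genes["chrom"] == seg.chrom)
                    & (genes["start"] < seg.end)
                    & (genes["end"] > seg.start)]
        names.append(",".join(hit.sort_values("start")["name"]))
    out["genes"] = names
    return out
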