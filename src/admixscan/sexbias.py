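"""Sex-biased admixture: the X-versus-autosome admixture difference ratio.

Because X chromosomes spend two thirds of their history in females, an
ancestry carried preferentially along the female (maternal) lineage is
over-represented on X relative to the autosomes.  The statistic

    delta = (F_X - F_auto) / F_total

per ancestry is positive under maternal excess and negative under paternal
excess of that ancestry.  Cohort-level fractions are pooled (covered-length
weighted means over individuals) before the ratio is taken, which keeps the
ratio stable when an ancestry is nearly absent in some individuals;
``per_individual=True`` switches to the mean of per-individual ratios.

Uncertainty is by bootstrap over individuals (percentile intervals) and the
two-sided bootstrap P-values carry the (k+1)/(B+1) add-one correction, so no
reported P can fall below 2/(B+1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .io import ANCESTRIES, ANCESTRY_INDEX
from .ancestry import GlobalAncestryRecord

__all__ = [
    "SexAsymmetryRecord", "delta_admix", "cohort_delta", "bootstrap_ci",
    "compare_populations", "test_nonzero",
]


@dataclass
class SexAsymmetryRecord:
    ancestry: str
    delta: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_individuals: int
    n_redrawn: int = 0


def delta_admix(f_x: float, f_auto: float, f_total: float) -> float:
    """(F_X - F_auto) / F_total; positive = maternal (female-lineage) excess."""
    for name, v in (("F_X", f_x), ("F_auto", f_auto), ("F_total", f_total)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if f_total == 0:
        raise ZeroDivisionError(
            "F_total is 0: ancestry absent, delta undefined")
    return (f_x - f_auto) / f_total


class _CohortArrays:
    """Vectorised view of a record list for fast resampling."""

    def __init__(self, records: list[GlobalAncestryRecord]):
        with_x = [r for r in records if r.F_X is not None]
        if len(with_x) < 2:
            raise ValueError("need >= 2 individuals with X-chromosome data")
        # canonical order: results are exactly invariant to input order
        with_x = sorted(with_x, key=lambda r: r.individual_id)
        self.records = with_x
        self.n = len(with_x)
        self.f_auto = np.array([r.F_auto for r in with_x])   # (n, 3)
        self.f_x = np.array([r.F_X for r in with_x])
        self.w_auto = np.array([r.auto_len for r in with_x])
        self.w_x = np.array([r.x_len for r in with_x])

    def delta(self, ancestry_idx: int, idx: np.ndarray | None = None,
              per_individual: bool = False) -> np.ndarray:
        """Cohort delta for index array ``idx`` of shape (..., n)."""
        if idx is None:
            idx = np.arange(self.n)
        a = self.f_auto[idx][..., ancestry_idx]
        x = self.f_x[idx][..., ancestry_idx]
        wa = self.w_auto[idx]
        wx = self.w_x[idx]
        if per_individual:
            f_tot = (wa * a + wx * x) / (wa + wx)
            with np.errstate(divide="ignore", invalid="ignore"):
                d = (x - a) / f_tot
            return d.mean(axis=-1)
        f_auto = (wa * a).sum(axis=-1) / wa.sum(axis=-1)
        f_x = (wx * x).sum(axis=-1) / wx.sum(axis=-1)
        f_tot = ((wa * a).sum(axis=-1) + (wx * x).sum(axis=-1)) \
            / (wa.sum(axis=-1) + wx.sum(axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            return (f_x - f_auto) / f_tot

    def f_total(self, ancestry_idx: int, idx: np.ndarray) -> np.ndarray:
        a = self.f_auto[idx][..., ancestry_idx]
        x = self.f_x[idx][..., ancestry_idx]
        wa = self.w_auto[idx]
        wx = self.w_x[idx]
        return ((wa * a).sum(axis=-1) + (wx * x).sum(axis=-1)) \
            / (wa.sum(axis=-1) + wx.sum(axis=-1))


def cohort_delta(records: list[GlobalAncestryRecord], ancestry: str,
                 per_individual: bool = False) -> float:
    """Cohort-level admixture difference ratio for one ancestry.

    F_X, F_auto and F_total are covered-length-weighted means over
    individuals (males contribute one X, females two, via their covered
    lengths), then the ratio is taken.  Invariant to individual order.
    """
    arrays = _CohortArrays(records)
    k = ANCESTRY_INDEX[ancestry]
    d = float(arrays.delta(k, per_individual=per_individual))
    if not np.isfinite(d):
        raise ZeroDivisionError(f"F_total is 0 for {ancestry}")
    return d


def _cohort_rng(records: list[GlobalAncestryRecord], seed: int) -> np.random.Generator:
    """Resampling stream keyed to the cohort's identity (sorted ids), so
    two-cohort comparisons are exactly invariant to argument order."""
    ids = "\n".join(sorted(r.individual_id for r in records))
    key = zlib.crc32(ids.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _bootstrap_deltas(arrays: _CohortArrays, k: int, n_boot: int,
                      rng: np.random.Generator,
                      per_individual: bool = False) -> tuple[np.ndarray, int]:
    """n_boot finite bootstrap deltas; replicates where the ancestry is
    entirely absent (F_total == 0) are redrawn, capped at 10x n_boot."""
    out = np.empty(n_boot)
    filled = 0
    redrawn = 0
    attempts = 0
    while filled < n_boot:
        want = n_boot - filled
        if attempts + want > 10 * n_boot:
            raise RuntimeError(
                "exceeded 10x n_boot resampling attempts; ancestry absent "
                "from nearly every replicate")
        idx = rng.integers(arrays.n, size=(want, arrays.n))
        d = arrays.delta(k, idx, per_individual=per_individual)
        ok = np.isfinite(d) & (arrays.f_total(k, idx) > 0)
        good = d[ok]
        out[filled:filled + len(good)] = good
        filled += len(good)
        redrawn += int((~ok).sum())
        attempts += want
    return out, redrawn


def bootstrap_ci(records: list[GlobalAncestryRecord], ancestry: str,
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 per_individual: bool = False) -> SexAsymmetryRecord:
    """Percentile bootstrap CI for the cohort delta (resampling individuals)."""
    if len([r for r in records if r.F_X is not None]) < 5:
        raise ValueError("need >= 5 individuals with X data for a bootstrap")
    arrays = _CohortArrays(records)
    k = ANCESTRY_INDEX[ancestry]
    point = float(arrays.delta(k, per_individual=per_individual))
    rng = _cohort_rng(records, seed)
    deltas, redrawn = _bootstrap_deltas(arrays, k, n_boot, rng, per_individual)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
    return SexAsymmetryRecord(ancestry, point, float(lo), float(hi),
                              n_boot, arrays.n, redrawn)


def _two_sided_p(diffs: np.ndarray, n_boot: int) -> float:
    k_le = int((diffs <= 0).sum())
    k_ge = int((diffs >= 0).sum())
    p = 2.0 * min(k_le + 1, k_ge + 1) / (n_boot + 1)
    return min(p, 1.0)


def compare_populations(records_a: list[GlobalAncestryRecord],
                        records_b: list[GlobalAncestryRecord],
                        ancestry: str, n_boot: int = 1000,
                        seed: int = 0) -> float:
    """Two-sided bootstrap P for delta_A != delta_B.

    Each cohort is resampled from its own identity-keyed stream; the P-value
    is 2 min(Pr(diff<=0), Pr(diff>=0)) with the (k+1)/(B+1) correction, so
    it is bounded below by 2/(B+1) and is exactly symmetric in (A, B).
    """
    for rec in (records_a, records_b):
        if len([r for r in rec if r.F_X is not None]) < 5:
            raise ValueError("both cohorts need >= 5 individuals with X data")
    k = ANCESTRY_INDEX[ancestry]
    arr_a, arr_b = _CohortArrays(records_a), _CohortArrays(records_b)
    d_a, _ = _bootstrap_deltas(arr_a, k, n_boot, _cohort_rng(records_a, seed))
    d_b, _ = _bootstrap_deltas(arr_b, k, n_boot, _cohort_rng(records_b, seed))
    return _two_sided_p(d_a - d_b, n_boot)


def test_nonzero(records: list[GlobalAncestryRecord], ancestry: str,
                 n_boot: int = 1000, seed: int = 0) -> float:
    """Two-sided bootstrap P for delta != 0 (same correction and floor)."""
    if len([r for r in records if r.F_X is not None]) < 5:
        raise ValueError("need >= 5 individuals with X data")
    k = ANCESTRY_INDEX[ancestry]
    arrays = _CohortArrays(records)
    deltas, _ = _bootstrap_deltas(arrays, k, n_boot, _cohort_rng(records, seed))
    return _two_sided_p(deltas, n_boot)


test_nonzero.__test__ = False  # not a pytest test despite the name


def asymmetry_table(records: list[GlobalAncestryRecord], n_boot: int = 1000,
                    level: float = 0.95, seed: int = 0):
    """Bootstrap summaries for all three ancestries as a DataFrame."""
    import pandas as pd

    rows = []
    for a in ANCESTRIES:
        rec = bootstrap_ci(records, a, n_boot=n_boot, level=level, seed=seed)
        p = test_nonzero(records, a, n_boot=n_boot, seed=seed)
        rows.append({"ancestry": a, "delta": rec.delta, "ci_low": rec.ci_low,
                     "ci_high": rec.ci_high, "p_nonzero": p,
                     "n_boot": rec.n_boot, "n": rec.n_individuals})
    return pd.DataFrame(rows)
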