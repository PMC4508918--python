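"""Global (genome-wide) ancestry estimation.

Two independent routes to per-individual three-way ancestry proportions:

1. tract-length aggregation of local-ancestry segments, split into
   autosomal / X / genome-wide compartments (the denominators exclude any
   uncovered sequence, so missing local-ancestry calls never dilute a
   fraction); and
2. supervised maximum-likelihood estimation from genotypes against fixed
   ancestral reference allele frequencies, via EM on the binomial admixture
   likelihood (the supervised analogue of an unsupervised k=3 model-based
   ancestry fit, made deterministic by fixing the reference frequencies).

Plus the classical cohort-structure view: pairwise allele-sharing distances
and their PCA projection (columns of the distance matrix standardised before
decomposition, i.e. a scaled PCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import ANCESTRIES, GenotypeMatrix, is_x_chrom


@dataclass
class DistanceMatrix:
    """Symmetric pairwise allele-sharing distance matrix in [0, 1]."""

    samples: list[str]
    values: np.ndarray    # (n, n), zero diagonal
    n_used: np.ndarray    # (n, n) count of SNPs compared per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class GlobalAncestryRecord:
    """Per-individual ancestry fractions by genomic compartment.

    Vectors are ordered (AFR, NAM, EUR); ``F_X`` is None when the individual
    has no X data.  ``auto_len``/``x_len`` are the covered base-pair
    denominators (per chromosome copy summed), used for cohort pooling.
    """

    individual_id: str
    sex: str | None
    F_total: np.ndarray
    F_auto: np.ndarray | None
    F_X: np.ndarray | None
    auto_len: float
    x_len: float
    source: str = "tracts"


def records_to_frame(records: list[GlobalAncestryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"individual": r.individual_id, "sex": r.sex, "source": r.source,
               "auto_len": r.auto_len, "x_len": r.x_len}
        for comp, vec in (("total", r.F_total), ("auto", r.F_auto), ("X", r.F_X)):
            for k, a in enumerate(ANCESTRIES):
                row[f"F_{comp}_{a}"] = np.nan if vec is None else float(vec[k])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele-sharing distance + PCA
# ---------------------------------------------------------------------------

def allele_sharing_distance(gm: GenotypeMatrix,
                            chunk_size: int = 2048) -> DistanceMatrix:
    """Pairwise allele-sharing distances: the fraction of allelic differences.

    Per SNP the contribution is |g_i/p_i - g_j/p_j| on the allele-frequency
    scale (for diploids, |dosage difference| / 2): identical calls add 0,
    opposite homozygotes add 1, het-vs-hom adds 1/2.  Averaged over the SNPs
    where both samples are non-missing; a pair sharing no non-missing SNP is
    an error naming the pair.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = gm.dosage / gm.ploidy
    valid = ~np.isnan(x)
    xf = np.where(valid, x, 0.0)
    n = gm.n_samples
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=np.int64)
    for lo in range(0, gm.n_snps, chunk_size):
        xs = xf[lo:lo + chunk_size]
        vs = valid[lo:lo + chunk_size]
        diff = np.abs(xs[:, :, None] - xs[:, None, :])
        both = vs[:, :, None] & vs[:, None, :]
        acc += np.where(both, diff, 0.0).sum(axis=0)
        cnt += both.sum(axis=0)
    off = ~np.eye(n, dtype=bool)
    if (cnt[off] == 0).any():
        i, j = np.argwhere((cnt == 0) & off)[0]
        raise ValueError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no "
            "non-missing SNPs")
    with np.errstate(invalid="ignore"):
        d = acc / cnt
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(gm.samples), d, cnt)


@dataclass
class PCAProjection:
    samples: list[str]
    coords: np.ndarray               # (n, n_components)
    explained_variance_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.samples, columns=cols)


def pca_project(distances: DistanceMatrix, n_components: int = 2) -> PCAProjection:
    """Scaled PCA of the distance matrix rows.

    Columns are centred and scaled to unit variance (ddof=1) before the
    decomposition, mirroring a scaled PCA of the full pairwise-distance
    matrix; zero-variance columns carry no information and are zeroed.
    """
    d = np.asarray(distances.values, dtype=float)
    n = d.shape[0]
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds {n} samples")
    mu = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    z = np.where(sd > 0, (d - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    return PCAProjection(list(distances.samples), coords,
                         pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# supervised admixture EM
# ---------------------------------------------------------------------------

class SupervisedAdmixtureEM(BaseEstimator):
    """Per-individual ancestry proportions from genotypes, references fixed.

    Model: with ancestry proportions q (a point on the 3-simplex) and
    reference ALT frequencies f_mk, the dosage at SNP m is
    Binomial(ploidy_m, sum_k q_k f_mk).  Each individual's q maximises this
    likelihood independently; EM ascends it by computing the expected number
    of alleles attributable to each ancestry and renormalising.  The
    log-likelihood is non-decreasing every iteration; iteration stops when
    every individual improves by less than ``tol`` or at ``max_iter`` (then a
    warning, not an error).  Initialisation is the uniform simplex point, so
    runs are deterministic; with reference frequencies identical across
    populations the likelihood is flat and the estimate stays uniform.

    Attributes (after ``fit``): ``proportions_`` (DataFrame, samples x
    ancestries), ``loglik_path_`` (per-iteration total log-likelihood),
    ``n_iter_``, ``converged_``, ``n_snps_used_``.
    """

    def __init__(self, tol: float = 1e-3, max_iter: int = 1000,
                 freq_clip: float = 1e-6):
        self.tol = tol
        self.max_iter = max_iter
        self.freq_clip = freq_clip

    def fit(self, gm: GenotypeMatrix, freqs: pd.DataFrame) -> "SupervisedAdmixtureEM":
        """Fit per-individual proportions.

        ``freqs`` is the allele-frequency table of :mod:`admixscan.io`;
        SNPs are matched to the genotype matrix on (chrom, pos) with REF/ALT
        required to agree.
        """
        variants = gm.variants.reset_index().rename(columns={"index": "_row"})
        merged = variants.merge(freqs, on=["chrom", "pos"], suffixes=("", "_f"))
        if "ref_f" in merged.columns:
            merged = merged[(merged["ref"] == merged["ref_f"])
                            & (merged["alt"] == merged["alt_f"])]
        if merged.empty:
            raise ValueError("no SNPs shared between genotypes and frequencies")
        rows = merged["_row"].to_numpy()
        f = merged[["freq_AFR", "freq_NAM", "freq_EUR"]].to_numpy()
        f = np.clip(f, self.freq_clip, 1.0 - self.freq_clip)
        g = gm.dosage[rows]
        p = gm.ploidy[rows].astype(float)
        valid = ~np.isnan(g)
        g = np.where(valid, g, 0.0)
        p = np.where(valid, p, 0.0)

        n = gm.n_samples
        q = np.full((n, 3), 1.0 / 3.0)
        ll_prev = np.full(n, -np.inf)
        path: list[float] = []
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            mu = f @ q.T                       # (m, n) expected ALT freq
            a = np.divide(g, mu, out=np.zeros_like(g), where=mu > 0)
            b = np.divide(p - g, 1.0 - mu, out=np.zeros_like(g),
                          where=(1.0 - mu) > 0)
            num = q * (f.T @ a).T + q * ((1.0 - f).T @ b).T
            q = num / num.sum(axis=1, keepdims=True)
            mu = f @ q.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = (np.where(g > 0, g * np.log(mu), 0.0)
                      + np.where(p - g > 0, (p - g) * np.log1p(-mu), 0.0)
                      ).sum(axis=0)
            path.append(float(ll.sum()))
            if np.all(np.abs(ll - ll_prev) < self.tol):
                self.converged_ = True
                ll_prev = ll
                break
            ll_prev = ll
        else:
            it = self.max_iter
        if not self.converged_:
            warnings.warn(f"EM did not converge in {self.max_iter} iterations",
                          stacklevel=2)
        self.n_iter_ = it
        self.loglik_path_ = np.asarray(path)
        self.loglik_ = ll_prev
        self.n_snps_used_ = len(rows)
        self.proportions_ = pd.DataFrame(q, index=list(gm.samples),
                                         columns=list(ANCESTRIES))
        return self


def supervised_admixture_em(gm: GenotypeMatrix, freqs: pd.DataFrame,
                            tol: float = 1e-3,
                            max_iter: int = 1000) -> pd.DataFrame:
    """Functional wrapper over :class:`SupervisedAdmixtureEM`."""
    return SupervisedAdmixtureEM(tol=tol, max_iter=max_iter).fit(gm, freqs).proportions_


# ---------------------------------------------------------------------------
# tract-length fractions
# ---------------------------------------------------------------------------

def fractions_from_tracts(segments: pd.DataFrame,
                          sexes: dict[str, str] | None = None,
                          include_x_in_total: bool = True,
                          ) -> list[GlobalAncestryRecord]:
    """Aggregate local-ancestry segments into per-individual global fractions.

    Per ancestry the fraction is covered length with that ancestry over
    total covered length, computed separately over autosomes, over X, and
    over their union (genome-wide); uncovered sequence is excluded from every
    denominator.  A compartment with zero covered length has its vector
    marked absent (None).  ``include_x_in_total=False`` makes the
    genome-wide vector autosomes-only.
    """
    records = []
    df = segments.assign(
        _len=segments["end"] - segments["start"],
        _x=segments["chrom"].map(is_x_chrom),
        _anc=segments["ancestry"].map({a: i for i, a in enumerate(ANCESTRIES)}),
    )
    for ind, grp in df.groupby("individual", sort=True):
        auto = np.zeros(3)
        x = np.zeros(3)
        for is_x, sub in grp.groupby("_x"):
            bucket = x if is_x else auto
            np.add.at(bucket, sub["_anc"].to_numpy(),
                      sub["_len"].to_numpy(dtype=float))
        total = auto + x if include_x_in_total else auto
        records.append(GlobalAncestryRecord(
            individual_id=str(ind),
            sex=(sexes or {}).get(str(ind)),
            F_total=total / total.sum() if total.sum() else None,
            F_auto=auto / auto.sum() if auto.sum() else None,
            F_X=x / x.sum() if x.sum() else None,
            auto_len=float(auto.sum()),
            x_len=float(x.sum()),
            source="tracts",
        ))
    return records
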