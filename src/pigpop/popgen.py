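"""Per-population diversity statistics, Fst estimators, genetic distances,
LD pruning, and PCA.

Two per-SNP Fst estimators are provided: the Weir–Cockerham (1984)
variance-components theta (default, with ratio-of-sums averaging) and the
Hudson/Bhatia ratio estimator.  Nucleotide diversity per site is the
unbiased pairwise heterozygosity pi_s = n/(n-1) * (1 - p^2 - q^2) with n
the number of called alleles, averaged over assayed SNPs — note this is a
per-assayed-SNP average, not sequence pi divided by genome length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence  # noqa: F401 - Sequence used in annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, PopulationGrouping

__all__ = [
    "DiversitySummary", "FstResult", "DistanceMatrix",
    "allele_frequency", "diversity_stats", "fst_per_snp",
    "pairwise_fst_matrix", "ibs_distance_matrix", "nei_standard_distance",
    "ld_prune", "pca", "PCAResult",
]


@dataclass
class DiversitySummary:
    """Breed-level diversity: polymorphism proportion, Ho, and pi."""

    population: str
    n_samples: int
    n_snp_polymorphic: int
    pn: float
    ho: float
    pi: float


@dataclass
class FstResult:
    """Per-SNP Fst between two groups; NaN marks undefined SNPs."""

    pair: tuple[str, str]
    per_snp: np.ndarray
    mean_fst: float
    estimator: str
    mean_fst_unweighted: float = float("nan")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.per_snp)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _group_dosages(ds: GenotypeDataset, group: Iterable[str]) -> np.ndarray:
    idx = ds.sample_indices(group)
    if len(idx) == 0:
        raise ValueError("empty sample group")
    return ds.dosages[idx]


def allele_frequency(
    ds: GenotypeDataset, group: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP alt-allele frequency within ``group``.

    Returns ``(freq, alt_count, total_alleles)``; ``freq`` is NaN where no
    alleles are called.
    """
    d = _group_dosages(ds, group)
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    freq = np.where(tot > 0, alt / np.where(tot > 0, tot, 1.0), np.nan)
    return freq, alt.astype(np.int64), tot.astype(np.int64)


def diversity_stats(
    ds: GenotypeDataset, group: Iterable[str], population: str = ""
) -> DiversitySummary:
    """PN, Ho, and pi for one group over all assayed SNPs.

    PN's denominator is the full assayed SNP count; Ho and pi average only
    over SNPs with at least one (Ho) / two (pi) called alleles in the group.
    """
    idx = ds.sample_indices(group)
    if len(idx) < 2:
        raise ValueError("diversity_stats requires a group of >= 2 samples (pi undefined)")
    d = ds.dosages[idx]
    called = d != MISSING
    n_called_gt = called.sum(axis=0)
    n_alleles = 2.0 * n_called_gt
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.where(n_alleles > 0, n_alleles, 1.0), np.nan)
    polymorphic = (alt > 0) & (alt < n_alleles)
    n_poly = int(polymorphic.sum())
    pn = n_poly / ds.n_variants

    het = (d == 1).sum(axis=0)
    ho_defined = n_called_gt > 0
    ho = float(np.mean(het[ho_defined] / n_called_gt[ho_defined])) if ho_defined.any() else 0.0

    pi_defined = n_alleles >= 2
    n_a = n_alleles[pi_defined]
    p_a = p[pi_defined]
    pi_s = n_a / (n_a - 1.0) * (1.0 - p_a**2 - (1.0 - p_a) ** 2)
    pi = float(pi_s.mean()) if pi_defined.any() else 0.0
    return DiversitySummary(
        population=population, n_samples=len(idx),
        n_snp_polymorphic=n_poly, pn=pn, ho=ho, pi=pi,
    )


def diversity_table(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-population diversity summary table (one row per breed)."""
    rows = []
    for pop, ids in ds.populations().items():
        if len(ids) < 2:
            continue
        s = diversity_stats(ds, ids, population=pop)
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _freq_het_counts(d: np.ndarray):
    called = d != MISSING
    n_gt = called.sum(axis=0).astype(float)      # called genotypes
    alt = np.where(called, d, 0).sum(axis=0).astype(float)
    het = (d == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_gt > 0, alt / (2.0 * np.where(n_gt > 0, n_gt, 1.0)), np.nan)
        h = np.where(n_gt > 0, het / np.where(n_gt > 0, n_gt, 1.0), np.nan)
    return p, h, n_gt


def _wc_components(d1: np.ndarray, d2: np.ndarray):
    """Weir–Cockerham (1984) a, b, c variance components, two populations."""
    p1, h1, n1 = _freq_het_counts(d1)
    p2, h2, n2 = _freq_het_counts(d2)
    r = 2.0
    valid = (n1 >= 1) & (n2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c, pbar


def _hudson_components(d1: np.ndarray, d2: np.ndarray):
    """Bhatia et al. Hudson-estimator numerator/denominator per SNP."""
    p1, _, ng1 = _freq_het_counts(d1)
    p2, _, ng2 = _freq_het_counts(d2)
    n1, n2 = 2.0 * ng1, 2.0 * ng2  # allele counts
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1.0)
            - p2 * (1 - p2) / (n2 - 1.0)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~valid] = np.nan
    den[~valid] = np.nan
    return num, den


def fst_per_snp(
    ds: GenotypeDataset,
    group_a: Iterable[str],
    group_b: Iterable[str],
    estimator: str = "weir_cockerham",
    labels: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Per-SNP Fst between two sample groups.

    A SNP is undefined (NaN) if either group has < 2 called alleles or the
    estimator denominator is 0 (monomorphic in the union).  ``mean_fst`` is
    the ratio-of-sums ("weighted") average over defined SNPs;
    ``mean_fst_unweighted`` is the plain mean of per-SNP values.
    """
    d1 = _group_dosages(ds, group_a)
    d2 = _group_dosages(ds, group_b)
    if estimator == "weir_cockerham":
        a, b, c, _ = _wc_components(d1, d2)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = _hudson_components(d1, d2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    # also require >=2 called alleles in each group
    n1 = 2 * (d1 != MISSING).sum(axis=0)
    n2 = 2 * (d2 != MISSING).sum(axis=0)
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(den) & (den != 0)
    per_snp = np.full(ds.n_variants, np.nan)
    per_snp[ok] = num[ok] / den[ok]
    mean = float(num[ok].sum() / den[ok].sum()) if ok.any() else float("nan")
    unweighted = float(np.nanmean(per_snp)) if ok.any() else float("nan")
    return FstResult(
        pair=labels, per_snp=per_snp, mean_fst=mean,
        estimator=estimator, mean_fst_unweighted=unweighted,
    )


def pairwise_fst_matrix(
    ds: GenotypeDataset,
    grouping: PopulationGrouping,
    estimator: str = "weir_cockerham",
) -> DistanceMatrix:
    """Average pairwise Fst between all groups, as a distance matrix.

    Negative mean Fst values (possible under Weir–Cockerham) are clamped
    to 0 for distance use; raw values live in the per-pair FstResult.
    """
    grouping.validate_against(ds)
    labels = sorted(grouping.members)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if len(grouping.members[lab]) < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = fst_per_snp(
                ds, grouping.members[labels[i]], grouping.members[labels[j]],
                estimator=estimator, labels=(labels[i], labels[j]),
            )
            mat[i, j] = mat[j, i] = max(res.mean_fst, 0.0)
    return DistanceMatrix(labels=labels, values=mat)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def ibs_distance_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """Individual-by-individual 1 - IBS-similarity matrix.

    similarity(i,j) = mean over SNPs called in both of (2 - |d_i - d_j|)/2.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = ds.dosages.astype(np.int16)
    called = d != MISSING
    n = ds.n_samples
    mat = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = np.abs(d[i] - d[i + 1:]).astype(float)
        overlap = both.sum(axis=1)
        if np.any(overlap == 0):
            bad = np.flatnonzero(overlap == 0) + i + 1
            raise ValueError(
                f"sample pairs with zero overlapping called SNPs: "
                f"({ds.sample_ids[i]}, {ds.sample_ids[bad[0]]})"
            )
        sim = ((2.0 - diff) / 2.0 * both).sum(axis=1) / overlap
        mat[i, i + 1:] = mat[i + 1:, i] = 1.0 - sim
    return DistanceMatrix(labels=ds.sample_ids, values=mat)


def nei_standard_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei standard genetic distance D from aligned alt-allele frequency vectors.

    D = -ln( sum_ij x_ij y_ij / sqrt(sum_ij x_ij^2 * sum_ij y_ij^2) ), with
    the inner sum over the two alleles of each biallelic SNP.  SNPs where
    either vector is NaN are skipped.  Disjoint allele sets everywhere give
    +inf with a warning.
    """
    x = np.asarray(freq_a, dtype=float)
    y = np.asarray(freq_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must be aligned on the same SNP set")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no SNPs with defined frequencies in both groups")
    jxy = float(np.sum(x * y + (1 - x) * (1 - y)))
    jx = float(np.sum(x**2 + (1 - x) ** 2))
    jy = float(np.sum(y**2 + (1 - y) ** 2))
    if jxy == 0.0:
        warnings.warn("no shared alleles at any locus; Nei D is infinite", UserWarning)
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(ds: GenotypeDataset, grouping: PopulationGrouping) -> DistanceMatrix:
    grouping.validate_against(ds)
    labels = sorted(grouping.members)
    freqs = {lab: allele_frequency(ds, grouping.members[lab])[0] for lab in labels}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = nei_standard_distance(freqs[labels[i]], freqs[labels[j]])
    return DistanceMatrix(labels=labels, values=mat)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pair_r2(d: np.ndarray, j: int, k: int) -> float:
    """Squared Pearson correlation of two dosage columns over shared calls."""
    both = (d[:, j] != MISSING) & (d[:, k] != MISSING)
    if both.sum() < 2:
        return float("nan")
    x = d[both, j].astype(float)
    y = d[both, k].astype(float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Slides windows of ``window_snps`` kept SNPs per chromosome advancing by
    ``step_snps``; while any in-window pair exceeds ``r2_max``, the member
    of the worst pair with the lower MAF (tie: later position) is dropped.
    Sweeps repeat until a full pass removes nothing, so the *surviving* set
    provably contains no within-window pair above the threshold.  Returns
    the kept variant indices.
    """
    if not window_snps > step_snps >= 1:
        raise ValueError("require window_snps > step_snps >= 1")
    from .io import variant_maf

    maf = variant_maf(ds)
    pos = ds.positions
    chroms = ds.chroms
    removed = np.zeros(ds.n_variants, dtype=bool)
    d = ds.dosages

    def drop_of(j: int, k: int) -> int:
        if maf[j] < maf[k]:
            return j
        if maf[k] < maf[j]:
            return k
        return j if pos[j] > pos[k] else k

    for chrom in dict.fromkeys(chroms):
        cidx = list(np.flatnonzero(chroms == chrom))
        while True:
            any_removed = False
            kept = [j for j in cidx if not removed[j]]
            start = 0
            while start < len(kept):
                active = [j for j in kept[start:] if not removed[j]][:window_snps]
                if len(active) >= 2:
                    while True:
                        worst, worst_r2 = None, r2_max
                        for ai in range(len(active)):
                            for bi in range(ai + 1, len(active)):
                                r2 = _pair_r2(d, active[ai], active[bi])
                                if not np.isnan(r2) and r2 > worst_r2:
                                    worst_r2, worst = r2, (active[ai], active[bi])
                        if worst is None:
                            break
                        drop = drop_of(*worst)
                        removed[drop] = True
                        active.remove(drop)
                        any_removed = True
                start += step_snps
            if not any_removed:
                break
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample scores from the genetic relationship matrix eigendecomposition."""

    scores: np.ndarray            # samples x components
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray
    sample_ids: list[str] = field(default_factory=list)


def pca(ds: GenotypeDataset, n_components: int = 4) -> PCAResult:
    """PCA of frequency-standardized dosages (GRM eigendecomposition).

    Missing dosages are mean-imputed per SNP before standardization.
    Scores are unit eigenvectors scaled by sqrt(eigenvalue); the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if ds.n_samples < n_components + 1:
        raise ValueError("need more samples than components")
    d = ds.dosages.astype(float)
    d[ds.dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; PCA undefined")
    d = d[:, poly]
    p = p[poly]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(np.isnan(z), 0.0, z)
    grm = z @ z.T / z.shape[1]
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        sign = np.sign(vecs[np.argmax(np.abs(vecs[:, k])), k])
        if sign < 0:
            vecs[:, k] = -vecs[:, k]
    total = np.maximum(np.linalg.eigvalsh(grm), 0.0).sum()
    scores = vecs * np.sqrt(vals)
    return PCAResult(
        scores=scores, eigenvalues=vals,
        explained_ratio=vals / total if total > 0 else vals,
        sample_ids=ds.sample_ids,
    )
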