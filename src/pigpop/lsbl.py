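"""Locus-specific branch length (LSBL) selection scan.

For three populations A, B, C with pairwise per-SNP Fst values, the branch
length specific to focal population A at a SNP is

    x = (Fst_AB + Fst_AC - Fst_BC) / 2.

Large x flags allele-frequency change private to A.  Outliers are called
either at an empirical tail quantile (default top 0.02% of defined x
values) or at an absolute cutoff; both modes are first-class because
published analyses mix the two readings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset, GeneAnnotation, SNPInfo
from .popgen import fst_per_snp


@dataclass
class LSBLResult:
    """Scan output for one focal population."""

    focal_group: str
    per_snp_x: np.ndarray
    threshold_value: float
    top_fraction: float
    outlier_flags: np.ndarray
    estimator: str = "weir_cockerham"
    fst_ab: np.ndarray | None = None
    fst_ac: np.ndarray | None = None
    fst_bc: np.ndarray | None = None

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())

    def to_frame(self, variants: list[SNPInfo] | None = None) -> pd.DataFrame:
        cols = {
            "fst_ab": self.fst_ab, "fst_ac": self.fst_ac, "fst_bc": self.fst_bc,
            "lsbl": self.per_snp_x, "outlier": self.outlier_flags,
        }
        df = pd.DataFrame({k: v for k, v in cols.items() if v is not None})
        if variants is not None:
            df.insert(0, "chrom", [v.chrom for v in variants])
            df.insert(1, "pos", [v.pos for v in variants])
            df.insert(2, "id", [v.id for v in variants])
        return df


def lsbl(fst_ab: np.ndarray, fst_ac: np.ndarray, fst_bc: np.ndarray) -> np.ndarray:
    """Elementwise x = (Fst_AB + Fst_AC - Fst_BC)/2; NaN propagates."""
    a, b, c = (np.asarray(v, dtype=float) for v in (fst_ab, fst_ac, fst_bc))
    if not (a.shape == b.shape == c.shape):
        raise ValueError("Fst vectors must be aligned on the same SNP index")
    return (a + b - c) / 2.0


def empirical_threshold(x: np.ndarray, top_fraction: float) -> float:
    """Outlier threshold: the value such that x > threshold selects the top
    ``floor(n_defined * top_fraction)`` defined values (ties may add more).

    With fewer than 1/top_fraction defined values the threshold is the
    maximum, selecting nothing.
    """
    vals = np.sort(x[~np.isnan(x)])[::-1]
    if vals.size == 0:
        return float("nan")
    k = int(np.floor(vals.size * top_fraction))
    if k == 0:
        return float(vals[0])
    return float(vals[k])


def run_three_population_scan(
    ds: GenotypeDataset,
    group_a,
    group_b,
    group_c,
    focal_label: str = "A",
    estimator: str = "weir_cockerham",
    top_fraction: float = 0.0002,
    abs_cutoff: float | None = None,
) -> LSBLResult:
    """Three-population LSBL scan with ``group_a`` focal.

    Groups must be disjoint with >= 2 samples each.  ``threshold_value`` is
    the empirical tail quantile of defined x values unless ``abs_cutoff``
    is given.  Undefined-Fst SNPs never become outliers.
    """
    sets = [frozenset(group_a), frozenset(group_b), frozenset(group_c)]
    for i in range(3):
        if len(sets[i]) < 2:
            raise ValueError("each group needs >= 2 samples")
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError(
                    f"scan groups overlap: {sorted(sets[i] & sets[j])[:5]}"
                )
    f_ab = fst_per_snp(ds, sets[0], sets[1], estimator=estimator, labels=("A", "B"))
    f_ac = fst_per_snp(ds, sets[0], sets[2], estimator=estimator, labels=("A", "C"))
    f_bc = fst_per_snp(ds, sets[1], sets[2], estimator=estimator, labels=("B", "C"))
    x = lsbl(f_ab.per_snp, f_ac.per_snp, f_bc.per_snp)
    threshold = abs_cutoff if abs_cutoff is not None else empirical_threshold(x, top_fraction)
    with np.errstate(invalid="ignore"):
        flags = x > threshold
    flags = np.where(np.isnan(x), False, flags)
    return LSBLResult(
        focal_group=focal_label, per_snp_x=x,
        threshold_value=float(threshold), top_fraction=top_fraction,
        outlier_flags=flags, estimator=estimator,
        fst_ab=f_ab.per_snp, fst_ac=f_ac.per_snp, fst_bc=f_bc.per_snp,
    )


@dataclass
class CandidateGeneSet:
    """Genes harbouring (inclusive) or within < flank of an outlier SNP."""

    genes: list[GeneAnnotation]
    support: dict[str, list[tuple[SNPInfo, float]]]
    flank_bp: int


def annotate_candidates(
    result: LSBLResult,
    snps: list[SNPInfo],
    genes: list[GeneAnnotation],
    flank_bp: int = 10_000,
    strict_chroms: bool = True,
) -> CandidateGeneSet:
    """Candidate genes near outlier SNPs.

    A gene qualifies iff some outlier SNP lies inside it (inclusive) or at
    distance strictly less than ``flank_bp`` from its nearest edge ("less
    than 10 kb" is strict: a SNP exactly 10,000 bp away does not count).
    Deduplicated by gene_id.
    """
    if len(snps) != result.per_snp_x.size:
        raise ValueError("SNP list does not match scan length")
    out_idx = np.flatnonzero(result.outlier_flags)
    out_snps = [snps[j] for j in out_idx]
    if strict_chroms and out_snps:
        unmatched = {s.chrom for s in out_snps} - {g.chrom for g in genes}
        if unmatched:
            raise ValueError(
                f"outlier SNP chromosomes absent from annotation: {sorted(unmatched)}"
            )
    support: dict[str, list[tuple[SNPInfo, float]]] = {}
    chosen: dict[str, GeneAnnotation] = {}
    for g in genes:
        for j in out_idx:
            s = snps[j]
            if s.chrom != g.chrom:
                continue
            dist = max(g.start_bp - s.pos, s.pos - g.end_bp, 0)
            if dist < flank_bp:
                chosen.setdefault(g.gene_id, g)
                support.setdefault(g.gene_id, []).append((s, float(result.per_snp_x[j])))
    return CandidateGeneSet(
        genes=list(chosen.values()), support=support, flank_bp=flank_bp
    )
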