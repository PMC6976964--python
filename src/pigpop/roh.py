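"""Sliding-window runs-of-homozygosity caller and length-bin classifier.

The caller mirrors the PLINK ``--homozyg`` scheme: windows of a fixed SNP
count slide along each chromosome; a window is called homozygous if it
contains at most ``window_het_max`` heterozygous and ``window_missing_max``
missing calls; each SNP's hit rate is the fraction of windows covering it
that are homozygous; runs of SNPs with hit rate >= ``window_hit_threshold``
become segments if they satisfy length, SNP-count, density, and gap
constraints.  Segments are trimmed to the outermost homozygous non-missing
SNPs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset


@dataclass
class ROHParams:
    """Caller parameters (defaults: PLINK --homozyg conventions).

    ``min_density_kb_per_snp`` caps segment sparsity: a segment must carry
    at least one SNP per that many kb.
    """

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    min_length_kb: float = 500.0
    min_snps: int = 100
    window_hit_threshold: float = 0.05
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snps < self.window_het_max + self.window_missing_max:
            raise ValueError("window_snps must be >= window_het_max + window_missing_max")
        for name in ("window_snps", "window_het_max", "window_missing_max",
                     "min_length_kb", "min_snps", "window_hit_threshold",
                     "max_gap_kb", "min_density_kb_per_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one individual (1-based inclusive bp)."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def _candidate_mask(dos: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-SNP candidate mask from window hit rates (one individual)."""
    n = dos.size
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (dos == 1).astype(np.int32)
    mis = (dos == MISSING).astype(np.int32)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(n - w + 1)
    hom_win = (
        (het_c[starts + w] - het_c[starts] <= params.window_het_max)
        & (mis_c[starts + w] - mis_c[starts] <= params.window_missing_max)
    ).astype(np.int32)
    hom_c = np.concatenate([[0], np.cumsum(hom_win)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    hits = hom_c[hi + 1] - hom_c[lo]
    denom = hi - lo + 1
    return hits / denom >= params.window_hit_threshold


def _runs(mask: np.ndarray):
    """Maximal True runs as (start, end) index pairs, inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def call_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every individual; deterministic in sample order."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chroms = ds.chroms
    pos_all = ds.positions
    max_gap_bp = params.max_gap_kb * 1000.0
    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        pos = pos_all[cidx]
        for si, sample in enumerate(ds.samples):
            dos = ds.dosages[si, cidx]
            cand = _candidate_mask(dos, params)
            for a, b in _runs(cand):
                # split at large inter-SNP gaps
                pieces = [(a, b)]
                gaps = np.flatnonzero(np.diff(pos[a : b + 1]) > max_gap_bp)
                if gaps.size:
                    pieces = []
                    lo = a
                    for g in gaps:
                        pieces.append((lo, a + g))
                        lo = a + g + 1
                    pieces.append((lo, b))
                for p, q in pieces:
                    seg = _emit(sample.id, chrom, pos, dos, p, q, params)
                    if seg is not None:
                        segments.append(seg)
    return segments


def _emit(sample, chrom, pos, dos, p, q, params) -> ROHSegment | None:
    # trim to outermost homozygous non-missing SNPs
    hom = (dos == 0) | (dos == 2)
    while p <= q and not hom[p]:
        p += 1
    while q >= p and not hom[q]:
        q -= 1
    if q < p:
        return None
    n_snps = q - p + 1
    length_kb = (pos[q] - pos[p] + 1) / 1000.0
    if length_kb < params.min_length_kb or n_snps < params.min_snps:
        return None
    if n_snps > 0 and length_kb / n_snps > params.min_density_kb_per_snp:
        return None
    return ROHSegment(
        sample=sample, chrom=str(chrom),
        start_bp=int(pos[p]), end_bp=int(pos[q]), n_snps=int(n_snps),
    )


#: Length-bin edges in Mb, half-open [lo, hi).
ROH_BINS: tuple[tuple[float, float], ...] = ((0.5, 1.0), (1.0, 5.0), (5.0, float("inf")))
ROH_BIN_LABELS = ("0.5-1Mb", "1-5Mb", ">5Mb")


def classify_roh(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """Per-sample counts and total kb in the three length bins."""
    rows: dict[str, dict[str, float]] = {}
    for seg in segments:
        rec = rows.setdefault(
            seg.sample,
            {f"n_{lab}": 0 for lab in ROH_BIN_LABELS}
            | {f"kb_{lab}": 0.0 for lab in ROH_BIN_LABELS}
            | {"kb_total": 0.0},
        )
        mb = seg.length_kb / 1000.0
        for (lo, hi), lab in zip(ROH_BINS, ROH_BIN_LABELS):
            if lo <= mb < hi:
                rec[f"n_{lab}"] += 1
                rec[f"kb_{lab}"] += seg.length_kb
                break
        rec["kb_total"] += seg.length_kb
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample").reset_index()
    return df.sort_values("sample").reset_index(drop=True)


def segments_to_frame(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": s.sample, "chrom": s.chrom, "start_bp": s.start_bp,
             "end_bp": s.end_bp, "n_snps": s.n_snps, "length_kb": s.length_kb}
            for s in segments
        ]
    )
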