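"""Region haplotype extraction, networks, shared-fixed blocks, sharing
matrices, tag-SNP reduction, and carrier quantitative-trait association.

Haplotype strings are over {0,1} in region SNP order; any haplotype with a
missing allele in the region is dropped (counted, not imputed).  The
network is a deterministic Kruskal minimum spanning tree under Hamming
distance, with co-minimal alternative edges retained as annotations —
randomized network layouts are replaced by a reproducible construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset, SNPInfo

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Distinct region haplotypes with per-population counts."""

    region: tuple[str, int, int]
    snps: list[SNPInfo]
    haplotypes: list[str]
    counts: pd.DataFrame          # haplotype x population
    n_dropped_missing: int = 0

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __post_init__(self) -> None:
        L = len(self.snps)
        if any(len(h) != L for h in self.haplotypes):
            raise ValueError("haplotype string length != region SNP count")


def extract_haplotypes(
    ds: GenotypeDataset, chrom: str, start_bp: int, end_bp: int
) -> HaplotypeTable:
    """Tabulate phased haplotypes over a region (1-based inclusive)."""
    if not ds.phased:
        raise ValueError(
            "haplotype extraction needs phased input; phase externally "
            "(e.g. BEAGLE/PHASE) or simulate phased data"
        )
    idx = ds.region_index(chrom, start_bp, end_bp)
    if idx.size == 0:
        raise ValueError(f"region {chrom}:{start_bp}-{end_bp} contains no SNPs")
    H = ds.haplotypes[:, idx]
    pops = [s.population for s in ds.samples for _ in (0, 1)]
    counts: dict[str, dict[str, int]] = {}
    dropped = 0
    for row, pop in zip(H, pops):
        if (row == MISSING).any():
            dropped += 1
            continue
        s = "".join("1" if a else "0" for a in row)
        counts.setdefault(s, {})
        counts[s][pop] = counts[s].get(pop, 0) + 1
    if not counts:
        raise ValueError("all haplotypes in region contain missing alleles")
    all_pops = list(dict.fromkeys(s.population for s in ds.samples))
    haps = sorted(counts)
    table = pd.DataFrame(
        [[counts[h].get(p, 0) for p in all_pops] for h in haps],
        index=haps, columns=all_pops, dtype=int,
    )
    tbl = HaplotypeTable(
        region=(chrom, start_bp, end_bp),
        snps=[ds.variants[j] for j in idx],
        haplotypes=haps, counts=table, n_dropped_missing=dropped,
    )
    # count conservation: every non-dropped phased haplotype is tabulated
    assert int(table.to_numpy().sum()) + dropped == 2 * ds.n_samples
    return tbl


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning-tree haplotype network.

    ``edges`` are the chosen MST edges (hap_a, hap_b, n_differences);
    ``alternative_edges`` are equal-weight edges that would close a cycle
    at the same Hamming distance (kept for display/interpretation).
    """

    nodes: pd.DataFrame           # counts table restricted to surviving haplotypes
    edges: list[tuple[str, str, int]]
    alternative_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for h in self.nodes.index:
            g.add_node(h, total=int(self.nodes.loc[h].sum()))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def haplotype_network(tbl: HaplotypeTable, min_count: int = 10) -> HaplotypeNetwork:
    """Deterministic Kruskal MST over haplotypes with total count > min_count.

    The frequency filter is strict ("greater than 10" keeps counts >= 11).
    Edges are examined in (weight, lexicographic endpoint pair) order.
    """
    totals = tbl.totals
    keep = [h for h in tbl.haplotypes if totals[h] > min_count]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 haplotypes with count > {min_count}; cannot build network"
        )
    cand = sorted(
        (hamming(a, b), a, b)
        for i, a in enumerate(keep) for b in keep[i + 1:]
    )
    parent = {h: h for h in keep}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges, alternatives = [], []
    for w, a, b in cand:
        ra, rb = find(a), find(b)
        if ra == rb:
            # annotate only co-minimal closures: an equal-weight edge whose
            # endpoints were connected at this same weight level
            alternatives.append((a, b, w))
            continue
        parent[ra] = rb
        edges.append((a, b, w))
    # keep only alternatives whose weight ties a chosen edge weight
    chosen_w = {w for _, _, w in edges}
    alternatives = [(a, b, w) for a, b, w in alternatives if w in chosen_w]
    return HaplotypeNetwork(
        nodes=tbl.counts.loc[keep], edges=edges, alternative_edges=alternatives
    )


@dataclass(frozen=True)
class SharedBlock:
    """Maximal run of SNPs fixed (>= fixation_min) for one shared allele in
    every target population."""

    snp_start_index: int
    snp_end_index: int
    start_bp: int
    end_bp: int
    n_snps: int
    shared_allele_string: str
    pop_block_freq: tuple[tuple[str, float], ...]

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def shared_fixed_blocks(
    ds: GenotypeDataset,
    chrom: str,
    start_bp: int,
    end_bp: int,
    target_pops: list[str],
    fixation_min: float = 0.95,
) -> list[SharedBlock]:
    """Detect maximal runs of SNPs where all target populations are nearly
    fixed for the same allele.

    Per SNP and target population the allele frequency is computed over
    that population's called phased alleles; a SNP is block-eligible iff a
    single allele reaches ``fixation_min`` in every target population.
    """
    if not target_pops:
        raise ValueError("empty target population set")
    if not ds.phased:
        raise ValueError("shared_fixed_blocks needs phased input")
    idx = ds.region_index(chrom, start_bp, end_bp)
    if idx.size == 0:
        raise ValueError("region contains no SNPs")
    pops = np.array([s.population for s in ds.samples for _ in (0, 1)])
    H = ds.haplotypes[:, idx].astype(float)
    H[H == MISSING] = np.nan
    pop_freq = {}
    for p in target_pops:
        rows = pops == p
        if int(rows.sum()) < 4:
            raise ValueError(f"target population {p!r} has < 4 haplotypes in region")
        with np.errstate(invalid="ignore"):
            pop_freq[p] = np.nanmean(H[rows], axis=0)   # alt-allele freq per SNP
    m = idx.size
    eligible = np.zeros(m, dtype=bool)
    allele = np.zeros(m, dtype=np.int8)
    for j in range(m):
        for a in (0, 1):
            fa = [pop_freq[p][j] if a == 1 else 1.0 - pop_freq[p][j] for p in target_pops]
            if all(not np.isnan(f) and f >= fixation_min for f in fa):
                eligible[j] = True
                allele[j] = a
                break
    pos = ds.positions[idx]
    blocks = []
    j = 0
    while j < m:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and eligible[k + 1]:
            k += 1
        astr = "".join(str(int(a)) for a in allele[j : k + 1])
        freqs = []
        for p in target_pops:
            f = [
                pop_freq[p][t] if allele[t] == 1 else 1.0 - pop_freq[p][t]
                for t in range(j, k + 1)
            ]
            freqs.append((p, float(np.mean(f))))
        blocks.append(
            SharedBlock(
                snp_start_index=int(j), snp_end_index=int(k),
                start_bp=int(pos[j]), end_bp=int(pos[k]),
                n_snps=int(k - j + 1), shared_allele_string=astr,
                pop_block_freq=tuple(freqs),
            )
        )
        j = k + 1
    return blocks


def haplotype_sharing_matrix(tbl: HaplotypeTable) -> pd.DataFrame:
    """Column-normalized haplotype frequencies per population.

    Populations with zero called haplotypes get an all-NaN column.
    """
    counts = tbl.counts.astype(float)
    colsum = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / colsum
    out.loc[:, colsum == 0] = np.nan
    return out


@dataclass
class AssociationResult:
    """Two-group trait comparison: F-test gate, then pooled or Welch t."""

    n_carrier: int
    mean_carrier: float
    sd_carrier: float
    n_noncarrier: int
    mean_noncarrier: float
    sd_noncarrier: float
    variance_p: float
    mean_p: float
    test_variant: str             # "pooled" or "welch"
    t_statistic: float

    def summary(self) -> str:
        return (
            f"{self.mean_carrier:.2f} ± {self.sd_carrier:.2f} versus "
            f"{self.mean_noncarrier:.2f} ± {self.sd_noncarrier:.2f}, "
            f"p = {self.mean_p:.2g} ({self.test_variant} t)"
        )


def carrier_association(
    carrier: np.ndarray, trait: np.ndarray, var_alpha: float = 0.05
) -> AssociationResult:
    """Compare trait means between carriers and noncarriers.

    A two-sided F-test on the variance ratio gates the t-test choice: equal
    variances not rejected at ``var_alpha`` -> pooled-variance t; rejected
    -> Welch.  Degenerate input (zero variance in both groups with equal
    means) yields NaN p-values.
    """
    carrier = np.asarray(carrier, dtype=bool)
    trait = np.asarray(trait, dtype=float)
    if carrier.shape != trait.shape:
        raise ValueError("carrier and trait vectors differ in length")
    if not np.isfinite(trait).all():
        raise ValueError("trait contains non-finite values")
    x = trait[carrier]
    y = trait[~carrier]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        var_p = float("nan")
        mean_p = float("nan") if x.mean() == y.mean() else 0.0
        return AssociationResult(
            n_carrier=len(x), mean_carrier=float(x.mean()), sd_carrier=0.0,
            n_noncarrier=len(y), mean_noncarrier=float(y.mean()), sd_noncarrier=0.0,
            variance_p=var_p, mean_p=mean_p, test_variant="pooled",
            t_statistic=float("nan"),
        )
    if vy == 0 or vx == 0:
        var_p = 0.0
    else:
        f = vx / vy
        cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
        var_p = float(2.0 * min(cdf, 1.0 - cdf))
    equal_var = var_p >= var_alpha
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return AssociationResult(
        n_carrier=len(x), mean_carrier=float(x.mean()), sd_carrier=float(x.std(ddof=1)),
        n_noncarrier=len(y), mean_noncarrier=float(y.mean()),
        sd_noncarrier=float(y.std(ddof=1)),
        variance_p=var_p, mean_p=float(p),
        test_variant="pooled" if equal_var else "welch", t_statistic=float(t),
    )


def tag_snp_reduction(tbl: HaplotypeTable, k: int | None = None):
    """Greedy tag-SNP selection distinguishing all haplotype pairs.

    Set cover over still-confounded haplotype pairs: repeatedly pick the
    SNP separating the most pairs (tie: smallest position).  Stops when all
    pairs are separated or ``k`` SNPs are chosen.  Returns (chosen region
    SNP indices, residual confounded pair count).
    """
    haps = tbl.haplotypes
    if len(haps) < 2:
        raise ValueError("need >= 2 haplotypes")
    L = len(tbl.snps)
    pairs = [(i, j) for i in range(len(haps)) for j in range(i + 1, len(haps))]
    unresolved = set(pairs)
    chosen: list[int] = []
    available = set(range(L))
    while unresolved and available and (k is None or len(chosen) < k):
        best_snp, best_gain = None, 0
        for s in sorted(available, key=lambda s: (tbl.snps[s].pos, s)):
            gain = sum(1 for (i, j) in unresolved if haps[i][s] != haps[j][s])
            if gain > best_gain:
                best_gain, best_snp = gain, s
        if best_snp is None:
            break
        chosen.append(best_snp)
        available.discard(best_snp)
        unresolved = {
            (i, j) for (i, j) in unresolved if haps[i][best_snp] == haps[j][best_snp]
        }
    return chosen, len(unresolved)


def haplotype_carrier_status(
    ds: GenotypeDataset, chrom: str, start_bp: int, end_bp: int, haplotype: str
) -> np.ndarray:
    """Dominant carrier coding: True iff a sample carries >= 1 copy of the
    reference haplotype over the region (missing-containing copies never match)."""
    if not ds.phased:
        raise ValueError("carrier status needs phased input")
    idx = ds.region_index(chrom, start_bp, end_bp)
    if idx.size != len(haplotype):
        raise ValueError(
            f"region holds {idx.size} SNPs but reference haplotype has {len(haplotype)}"
        )
    ref = np.array([int(c) for c in haplotype], dtype=np.int8)
    H = ds.haplotypes[:, idx]
    match = np.all(H == ref, axis=1)
    return match[0::2] | match[1::2]
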