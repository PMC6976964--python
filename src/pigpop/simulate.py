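"""Multi-population genotype/haplotype simulation with plantable signals.

The drift model is Balding–Nichols: per SNP an ancestral frequency p is
drawn (Uniform(0.05, 0.95) by default) and each population's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F), so the drift parameter F equals the expected
Fst of that population against the ancestor.  Two genotype modes:

* ``independent`` — haplotype alleles Bernoulli(pop frequency) per SNP, no
  LD (the null for LD sanity checks and for the selection-scan null).
* ``mosaic`` — each population holds a small founder-haplotype panel and
  individual haplotypes are Markov copies of founders with a per-bp switch
  probability, giving distance-decaying LD and discrete haplotypes into
  which blocks can be planted.

Plantable signals: selected outlier SNPs (frequency override in a focal
population), shared haplotype blocks at chosen frequencies in chosen
populations, ROH tracts (second haplotype overwritten by the first), and a
quantitative trait with an additive carrier effect plus Gaussian noise.
All generators are pure functions of (config, seed).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, SampleInfo, SNPInfo

logger = logging.getLogger(__name__)

#: Mean inter-SNP spacing (bp) of the chip this emulates.
DEFAULT_SPACING_BP = 2689


@dataclass
class SelectedLocus:
    """Frequency override at one SNP in one focal population.

    ``ancestral_freq``, when set, pins the ancestral frequency at the SNP
    so the non-focal populations drift around a known value — the planted
    sweep is then a controlled frequency shift in the focal population
    against that background.
    """

    snp_index: int
    focal_pop: int                # population index
    target_freq: float
    ancestral_freq: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_freq <= 1.0:
            raise ValueError("target_freq must be in [0, 1]")
        if self.ancestral_freq is not None and not 0.0 < self.ancestral_freq < 1.0:
            raise ValueError("ancestral_freq must be in (0, 1)")


@dataclass
class PlantedBlock:
    """A founder haplotype planted over a SNP-index range in target pops."""

    snp_start: int
    snp_end: int                  # inclusive
    target_pops: list[int]
    frequency: float = 1.0
    haplotype: str | None = None  # defaults to all-'1' over the block


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic dataset.  ``seed`` is mandatory."""

    n_pops: int = 3
    n_per_pop: int = 15
    n_snps: int = 1000
    drift_F: float | Sequence[float] = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    mode: str = "independent"     # or "mosaic"
    n_founders: int = 8
    switch_rate_per_bp: float = 2e-6
    mean_spacing_bp: int = DEFAULT_SPACING_BP
    chrom: str = "1"
    phased: bool = True
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    seed: int | None = None

    def drift_vector(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.drift_F, dtype=float), (self.n_pops,)).copy()
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("drift_F must be in (0, 1): F=0 or 1 degenerates the Beta")
        return f

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.mode not in ("independent", "mosaic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.drift_vector()


def _positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    gaps = rng.integers(1, 2 * cfg.mean_spacing_bp, size=cfg.n_snps)
    return np.cumsum(gaps)


def _pop_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=cfg.n_snps)
    for sel in cfg.selected_loci:
        if sel.ancestral_freq is not None:
            p[sel.snp_index] = sel.ancestral_freq
    f = cfg.drift_vector()
    freqs = np.empty((cfg.n_pops, cfg.n_snps))
    for k in range(cfg.n_pops):
        a = p * (1 - f[k]) / f[k]
        b = (1 - p) * (1 - f[k]) / f[k]
        freqs[k] = rng.beta(a, b)
    for sel in cfg.selected_loci:
        freqs[sel.focal_pop, sel.snp_index] = sel.target_freq
    return freqs


def simulate_populations(cfg: SimulationConfig) -> GenotypeDataset:
    """Simulate K drifted populations of diploids (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    pos = _positions(cfg, rng)
    freqs = _pop_frequencies(cfg, rng)
    n_total = cfg.n_pops * cfg.n_per_pop
    haps = np.empty((2 * n_total, cfg.n_snps), dtype=np.int8)
    samples: list[SampleInfo] = []
    for k in range(cfg.n_pops):
        pop = f"POP{k + 1}"
        row0 = 2 * k * cfg.n_per_pop
        if cfg.mode == "independent":
            haps[row0 : row0 + 2 * cfg.n_per_pop] = (
                rng.random((2 * cfg.n_per_pop, cfg.n_snps)) < freqs[k]
            ).astype(np.int8)
        else:
            founders = (rng.random((cfg.n_founders, cfg.n_snps)) < freqs[k]).astype(np.int8)
            haps[row0 : row0 + 2 * cfg.n_per_pop] = _mosaic_copy(
                founders, 2 * cfg.n_per_pop, pos, cfg.switch_rate_per_bp, rng
            )
        samples += [
            SampleInfo(id=f"{pop}_{i + 1:03d}", population=pop)
            for i in range(cfg.n_per_pop)
        ]
    variants = [
        SNPInfo(id=f"snp{j + 1}", chrom=cfg.chrom, pos=int(pos[j]))
        for j in range(cfg.n_snps)
    ]
    dosages = haps[0::2] + haps[1::2]
    return GenotypeDataset(
        variants=variants, samples=samples, dosages=dosages,
        phased=cfg.phased, haplotypes=haps if cfg.phased else None,
    )


def _mosaic_copy(founders, n_haps, pos, switch_rate, rng) -> np.ndarray:
    """Li–Stephens-like copying: founder index is a Markov chain along SNPs
    with switch probability 1 - exp(-rate * gap_bp)."""
    nf, m = founders.shape
    gaps = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    out = np.empty((n_haps, m), dtype=np.int8)
    for h in range(n_haps):
        src = rng.integers(nf)
        out[h, 0] = founders[src, 0]
        switches = rng.random(m - 1) < p_switch
        for j in range(1, m):
            if switches[j - 1]:
                src = rng.integers(nf)
            out[h, j] = founders[src, j]
    return out


def simulate_haplotype_region(cfg: SimulationConfig) -> GenotypeDataset:
    """Mosaic-mode simulation with planted haplotype blocks realized.

    Within each target population, round(frequency * 2n) haplotypes are
    overwritten with the designated block haplotype over the exact SNP-index
    range; the realized frequency is logged when rounding moves it.
    """
    if cfg.mode != "mosaic":
        raise ValueError("planted haplotype blocks require mosaic mode")
    ds = simulate_populations(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
    haps = ds.haplotypes.copy()
    pop_of = np.array([s.population for s in ds.samples for _ in (0, 1)])
    for blk in cfg.planted_blocks:
        width = blk.snp_end - blk.snp_start + 1
        hstr = blk.haplotype or "1" * width
        if len(hstr) != width:
            raise ValueError("planted haplotype length != block width")
        ref = np.array([int(c) for c in hstr], dtype=np.int8)
        for k in blk.target_pops:
            pop = f"POP{k + 1}"
            rows = np.flatnonzero(pop_of == pop)
            n_copy = int(round(blk.frequency * rows.size))
            if abs(n_copy - blk.frequency * rows.size) > 1e-9:
                logger.info(
                    "planted block frequency %.3f rounded to %d/%d haplotypes in %s",
                    blk.frequency, n_copy, rows.size, pop,
                )
            chosen = rng.choice(rows, size=n_copy, replace=False)
            haps[np.ix_(chosen, np.arange(blk.snp_start, blk.snp_end + 1))] = ref
    return GenotypeDataset(
        variants=ds.variants, samples=ds.samples,
        dosages=haps[0::2] + haps[1::2], phased=True, haplotypes=haps,
    )


def plant_roh(
    ds: GenotypeDataset, tracts: list[tuple[str, str, int, int]]
) -> GenotypeDataset:
    """Force homozygosity in tracts (sample_id, chrom, start_bp, end_bp).

    The second haplotype is overwritten by the first inside each tract;
    overlapping tracts for one sample are merged with a log entry.
    """
    if not ds.phased:
        raise ValueError("plant_roh needs phased input")
    merged: dict[tuple[str, str], list[list[int]]] = {}
    for sid, chrom, start, end in tracts:
        key = (sid, chrom)
        spans = merged.setdefault(key, [])
        for span in spans:
            if start <= span[1] and end >= span[0]:
                logger.warning("merging overlapping ROH tracts for %s", sid)
                span[0], span[1] = min(span[0], start), max(span[1], end)
                break
        else:
            spans.append([start, end])
    haps = ds.haplotypes.copy()
    for (sid, chrom), spans in merged.items():
        i = ds.sample_indices([sid])[0]
        for start, end in spans:
            idx = ds.region_index(chrom, start, end)
            haps[2 * i + 1, idx] = haps[2 * i, idx]
    return GenotypeDataset(
        variants=ds.variants, samples=ds.samples,
        dosages=haps[0::2] + haps[1::2], phased=True, haplotypes=haps,
    )


def simulate_trait(
    ds: GenotypeDataset,
    chrom: str,
    start_bp: int,
    end_bp: int,
    haplotype: str,
    beta: float,
    residual_sd: float,
    seed: int,
    mu: float = 138.0,
) -> pd.DataFrame:
    """Quantitative trait y = mu + beta * carrier + N(0, residual_sd).

    Carrier status is dominant: >= 1 copy of the reference haplotype.  The
    default baseline emulates a hemoglobin-like trait in g/L.
    """
    from .haplotypes import haplotype_carrier_status

    carrier = haplotype_carrier_status(ds, chrom, start_bp, end_bp, haplotype)
    rng = np.random.default_rng(seed)
    y = mu + beta * carrier.astype(float) + rng.normal(0.0, residual_sd, ds.n_samples)
    return pd.DataFrame(
        {"sample_id": ds.sample_ids, "trait": y, "carrier": carrier}
    )


def write_truth(cfg: SimulationConfig, path: str | Path) -> None:
    """Record planted signals as JSON for downstream assertions."""
    truth = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "drift_F": list(cfg.drift_vector()),
        "selected_loci": [
            {"snp_index": s.snp_index, "focal_pop": s.focal_pop,
             "target_freq": s.target_freq}
            for s in cfg.selected_loci
        ],
        "planted_blocks": [
            {"snp_start": b.snp_start, "snp_end": b.snp_end,
             "target_pops": b.target_pops, "frequency": b.frequency,
             "haplotype": b.haplotype}
            for b in cfg.planted_blocks
        ],
    }
    Path(path).write_text(json.dumps(truth, indent=2))
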