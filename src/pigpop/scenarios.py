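"""Canonical synthetic study designs used for power and calibration checks.

These freeze the simulation conditions that emulate the study this package
re-implements: a focal breed scanned against two pooled multi-breed
contrast groups, an equal-drift null, and a region carrying a haplotype
block fixed in a subset of populations.  Tests and the acceptance script
share these definitions so every reported number refers to one design.
"""
from __future__ import annotations

import numpy as np

from .io import GenotypeDataset
from .lsbl import LSBLResult, run_three_population_scan
from .simulate import (
    PlantedBlock, SelectedLocus, SimulationConfig, simulate_haplotype_region,
    simulate_populations,
)

#: Index of the planted sweep SNP in the scan scenarios.
SWEEP_SNP = 123


def sweep_scan_config(seed: int, n_snps: int = 20_000) -> SimulationConfig:
    """Pooled three-group contrast with one planted sweep.

    20 breeds of 15 animals drifted at F=0.1; the focal breed carries a
    selected locus driven from an ancestral frequency of 0.2 to 0.99.
    Groups mirror the study design: A = the focal breed, B = breeds 2-10
    pooled, C = breeds 11-20 pooled.
    """
    return SimulationConfig(
        n_pops=20, n_per_pop=15, n_snps=n_snps, drift_F=0.1, seed=seed,
        phased=False,
        selected_loci=[SelectedLocus(SWEEP_SNP, 0, 0.99, ancestral_freq=0.2)],
    )


def pooled_groups(ds: GenotypeDataset) -> tuple[list[str], list[str], list[str]]:
    pops = ds.populations()
    a = pops["POP1"]
    b = [s for k in range(2, 11) for s in pops[f"POP{k}"]]
    c = [s for k in range(11, 21) for s in pops[f"POP{k}"]]
    return a, b, c


def run_sweep_scan(seed: int, estimator: str = "hudson") -> LSBLResult:
    """One sweep-scenario replicate scanned at the top-0.02% threshold.

    The Hudson estimator is the default here because the contrast groups
    are breed pools roughly ten times the focal sample size — the regime
    where the Weir–Cockerham two-population theta is known to be biased by
    unequal sample sizes and by the pools' internal structure.
    """
    ds = simulate_populations(sweep_scan_config(seed))
    a, b, c = pooled_groups(ds)
    return run_three_population_scan(ds, a, b, c, estimator=estimator)


def null_scan_config(seed: int, drift_F: float, n_snps: int = 20_000) -> SimulationConfig:
    """Equal-drift null: three populations of 15, no selection."""
    return SimulationConfig(
        n_pops=3, n_per_pop=15, n_snps=n_snps, drift_F=drift_F, seed=seed,
        phased=False,
    )


def run_null_scan(seed: int, drift_F: float, abs_cutoff: float = 0.8) -> LSBLResult:
    ds = simulate_populations(null_scan_config(seed, drift_F))
    pops = ds.populations()
    return run_three_population_scan(
        ds, pops["POP1"], pops["POP2"], pops["POP3"], abs_cutoff=abs_cutoff
    )


#: Planted shared-block design: 12 populations, block fixed in 5 of them.
BLOCK_SNP_START, BLOCK_SNP_END = 80, 105
BLOCK_TARGETS = [f"POP{k}" for k in range(1, 6)]


def shared_block_config(seed: int, frequency: float = 1.0) -> SimulationConfig:
    """Region design for block detection: chip-like common ancestral
    frequencies (0.2-0.8) and a 12-founder mosaic panel keep chance
    same-allele fixation across the five targets negligible."""
    return SimulationConfig(
        n_pops=12, n_per_pop=10, n_snps=200, drift_F=0.05, seed=seed,
        mode="mosaic", n_founders=12, ancestral_freq_range=(0.2, 0.8),
        planted_blocks=[
            PlantedBlock(BLOCK_SNP_START, BLOCK_SNP_END, [0, 1, 2, 3, 4],
                         frequency=frequency)
        ],
    )


def make_shared_block_dataset(seed: int, frequency: float = 1.0) -> GenotypeDataset:
    return simulate_haplotype_region(shared_block_config(seed, frequency))
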