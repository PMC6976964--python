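"""Shared fixtures: small hand-built datasets and VCF writers."""
from __future__ import annotations

import numpy as np
import pytest

from pigpop.io import MISSING, GenotypeDataset, SampleInfo, SNPInfo


def make_dataset(
    dosages,
    positions=None,
    chrom="1",
    populations=None,
    phased=False,
    haplotypes=None,
    spacing=1000,
):
    """Build a GenotypeDataset from a dosage matrix (rows = samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [(j + 1) * spacing for j in range(m)]
    if populations is None:
        populations = ["P1"] * n
    variants = [
        SNPInfo(id=f"snp{j + 1}", chrom=chrom, pos=int(positions[j])) for j in range(m)
    ]
    samples = [
        SampleInfo(id=f"S{i + 1}", population=populations[i]) for i in range(n)
    ]
    if phased and haplotypes is None:
        # derive trivial phase: dosage 1 -> (0,1)
        haplotypes = np.zeros((2 * n, m), dtype=np.int8)
        for i in range(n):
            for j in range(m):
                d = dosages[i, j]
                if d == MISSING:
                    haplotypes[2 * i, j] = haplotypes[2 * i + 1, j] = MISSING
                elif d == 1:
                    haplotypes[2 * i, j], haplotypes[2 * i + 1, j] = 0, 1
                else:
                    haplotypes[2 * i, j] = haplotypes[2 * i + 1, j] = d // 2
    return GenotypeDataset(
        variants=variants, samples=samples, dosages=dosages,
        phased=phased, haplotypes=haplotypes if phased else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def write_popmap_file(path, samples):
    lines = ["sample_id\tpopulation\tecotype"]
    for sid, pop in samples:
        lines.append(f"{sid}\t{pop}\t")
    path.write_text("\n".join(lines) + "\n")
    return path
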