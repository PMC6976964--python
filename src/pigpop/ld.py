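"""Pairwise genotype r², LD-decay curve fitting, and the r0.3² statistic.

r² is the squared Pearson correlation of dosage vectors (composite LD on
genotypes, matching PLINK ``--r2``).  The decay curve is the Sved/Heifetz
expectation E[r² | d] = 1 / (1 + rate·d); r0.3² — the distance at which the
fitted curve equals 0.3 — follows in closed form as (1/0.3 − 1)/rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import MISSING, GenotypeDataset


@dataclass
class LDDecayFit:
    """Fitted per-kb decay rate and the implied r0.3² distance (kb)."""

    rate: float
    r03_kb: float


def r03_from_rate(rate: float) -> float:
    """Distance (kb) at which 1/(1+rate·d) = 0.3; +inf when rate -> 0."""
    if rate <= 0:
        return float("inf")
    return (1.0 / 0.3 - 1.0) / rate


def compute_ld_pairs(
    ds: GenotypeDataset,
    group: Iterable[str],
    maf_min: float = 0.1,
    call_rate_min: float = 0.9,
    max_window_kb: float = 1000.0,
    report_r2_min: float = 0.0,
) -> pd.DataFrame:
    """All within-chromosome SNP-pair r² values at distance <= the window.

    SNPs are pre-filtered within the group: MAF > ``maf_min`` and call rate
    > ``call_rate_min`` (both strict), and zero-variance SNPs are excluded.
    Pairs with r² < ``report_r2_min`` are suppressed (use 0.3 to mirror the
    PLINK-style report; keep 0 when the result feeds the decay fit).
    Returns a frame with columns chrom, pos_a, pos_b, dist_bp, r2.
    """
    idx = ds.sample_indices(group)
    if len(idx) < 2:
        raise ValueError("need >= 2 samples")
    d = ds.dosages[idx].astype(float)
    d[d == MISSING] = np.nan
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(p, 1 - p)
    cr = n_called / len(idx)
    var = np.nanvar(d, axis=0)
    keep = (maf > maf_min) & (cr > call_rate_min) & (var > 0) & (n_called >= 2)

    chroms = ds.chroms
    pos = ds.positions
    max_bp = max_window_kb * 1000.0
    rows = []
    for chrom in dict.fromkeys(chroms):
        cj = np.flatnonzero((chroms == chrom) & keep)
        cp = pos[cj]
        for a in range(len(cj)):
            hi = np.searchsorted(cp, cp[a] + max_bp, side="right")
            for b in range(a + 1, hi):
                x, y = d[:, cj[a]], d[:, cj[b]]
                both = ~(np.isnan(x) | np.isnan(y))
                if both.sum() < 2:
                    continue
                xv, yv = x[both], y[both]
                if xv.std() == 0 or yv.std() == 0:
                    continue
                r = np.corrcoef(xv, yv)[0, 1]
                r2 = r * r
                if r2 >= report_r2_min:
                    rows.append((chrom, int(cp[a]), int(cp[b]), int(cp[b] - cp[a]), r2))
    return pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "dist_bp", "r2"])


def fit_decay(pairs: pd.DataFrame) -> LDDecayFit:
    """Nonlinear least-squares fit of r² against 1/(1 + rate·d_kb).

    Requires >= 10 pairs over >= 2 distinct distances.  A degenerate fit
    (rate indistinguishable from 0, no decay within the window) reports
    r0.3² as +inf with a warning.
    """
    if len(pairs) < 10 or pairs["dist_bp"].nunique() < 2:
        raise ValueError("need >= 10 pairs spanning >= 2 distinct distances")
    d_kb = pairs["dist_bp"].to_numpy(dtype=float) / 1000.0
    r2 = pairs["r2"].to_numpy(dtype=float)

    def model(d, rate):
        return 1.0 / (1.0 + rate * d)

    popt, _ = curve_fit(model, d_kb, r2, p0=[0.01], bounds=(1e-12, np.inf), maxfev=10000)
    rate = float(popt[0])
    # degenerate: the fitted curve barely moves across the observed window
    if model(d_kb.max(), rate) > 0.99:
        warnings.warn("no detectable LD decay within the window; r0.3 is infinite",
                      UserWarning)
        return LDDecayFit(rate=rate, r03_kb=float("inf"))
    return LDDecayFit(rate=rate, r03_kb=r03_from_rate(rate))


def r03_from_binned(pairs: pd.DataFrame, bin_kb: float = 10.0) -> float:
    """r0.3² read off binned mean r² (alternative to the fitted mode).

    Linear interpolation between the last bin with mean r² >= 0.3 and the
    first below; +inf if the means never fall below 0.3.
    """
    d_kb = pairs["dist_bp"].to_numpy(dtype=float) / 1000.0
    r2 = pairs["r2"].to_numpy(dtype=float)
    bins = np.floor(d_kb / bin_kb).astype(int)
    centers, means = [], []
    for b in np.unique(bins):
        centers.append((b + 0.5) * bin_kb)
        means.append(r2[bins == b].mean())
    centers, means = np.array(centers), np.array(means)
    below = np.flatnonzero(means < 0.3)
    if below.size == 0:
        return float("inf")
    k = below[0]
    if k == 0:
        return float(centers[0])
    x0, x1 = centers[k - 1], centers[k]
    y0, y1 = means[k - 1], means[k]
    return float(x0 + (y0 - 0.3) / (y0 - y1) * (x1 - x0))
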