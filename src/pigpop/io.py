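"""Genotype data model, readers/writers, and variant/sample filters.

The central container is :class:`GenotypeDataset`: a samples x variants
matrix of alt-allele dosages (0/1/2, with a distinguished ``MISSING``
sentinel), variant metadata, a population map, and — when the input is
phased — a 2·samples x variants haplotype matrix.  Coordinates are 1-based
inclusive throughout (VCF convention); BED intervals are converted on read.
"""
from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele/genotype.  Never 0 — a 0 dosage is a real
#: homozygous-reference call.
MISSING: int = -1


@dataclass(frozen=True)
class SNPInfo:
    """One biallelic SNP. ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class SampleInfo:
    """One diploid individual with its population (breed) label."""

    id: str
    population: str
    ecotype: str | None = None

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"sample {self.id}: population label must be non-empty")


@dataclass
class PopulationGrouping:
    """Named, disjoint grouping of sample ids (e.g. the A/B/C scan groups)."""

    name: str
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, ids in self.members.items():
            ids = frozenset(ids)
            self.members[label] = ids
            overlap = seen & ids
            if overlap:
                raise ValueError(
                    f"grouping {self.name!r}: groups are not disjoint "
                    f"(shared ids: {sorted(overlap)[:5]})"
                )
            seen |= ids

    def validate_against(self, ds: "GenotypeDataset") -> None:
        known = set(ds.sample_ids)
        missing = {i for ids in self.members.values() for i in ids} - known
        if missing:
            raise ValueError(
                f"grouping {self.name!r}: ids not in dataset: {sorted(missing)[:10]}"
            )


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes for a set of samples.

    ``dosages[i, j]`` counts alt alleles (0/1/2) of sample *i* at variant
    *j*, or :data:`MISSING`.  When ``phased``, ``haplotypes`` holds the two
    haplotypes of sample *i* in rows ``2i`` and ``2i+1`` with entries in
    {0, 1, MISSING}, and dosages are consistent with their sum wherever
    both alleles are called.
    """

    variants: list[SNPInfo]
    samples: list[SampleInfo]
    dosages: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = len(self.samples), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} != (samples={n}, variants={m})"
            )
        ids = [s.id for s in self.samples]
        if len(set(ids)) != n:
            raise ValueError("sample ids are not unique")
        self._check_sorted()
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased dataset requires a haplotype matrix")
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n, m):
                raise ValueError(
                    f"haplotype matrix shape {self.haplotypes.shape} != (2*{n}, {m})"
                )
            h1, h2 = self.haplotypes[0::2], self.haplotypes[1::2]
            both = (h1 != MISSING) & (h2 != MISSING)
            if not np.array_equal((h1 + h2)[both], self.dosages[both]):
                raise ValueError("dosages inconsistent with haplotype sums")
            if not np.all(self.dosages[~both] == MISSING):
                raise ValueError("missing haplotype alleles must propagate to dosage")

    def _check_sorted(self) -> None:
        # positions strictly increase within a chromosome; equal positions
        # are tolerated only for distinct allele pairs (split multiallelics)
        last: SNPInfo | None = None
        for v in self.variants:
            if last is not None and last.chrom == v.chrom:
                if v.pos < last.pos:
                    raise ValueError(
                        f"variants not position-sorted at {v.chrom}:{v.pos}"
                    )
                if v.pos == last.pos and (v.ref_allele, v.alt_allele) == (
                    last.ref_allele, last.alt_allele
                ):
                    raise ValueError(
                        f"duplicate variant at {v.chrom}:{v.pos} "
                        f"{v.ref_allele}>{v.alt_allele}"
                    )
            last = v

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s.id: i for i, s in enumerate(self.samples)}
        unknown = [i for i in ids if i not in lookup]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:10]}")
        return np.array(sorted(lookup[i] for i in ids), dtype=np.intp)

    def populations(self) -> dict[str, list[str]]:
        """Population label -> sample ids, in dataset order."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.population, []).append(s.id)
        return out

    def population_grouping(self, name: str = "all_breeds") -> PopulationGrouping:
        return PopulationGrouping(
            name, {p: frozenset(ids) for p, ids in self.populations().items()}
        )

    def subset(
        self,
        variant_idx: Sequence[int] | np.ndarray | None = None,
        sample_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        hap = None
        if self.phased:
            hrows = np.empty(2 * len(si), dtype=np.intp)
            hrows[0::2] = 2 * si
            hrows[1::2] = 2 * si + 1
            hap = self.haplotypes[np.ix_(hrows, vi)]
        return GenotypeDataset(
            variants=[self.variants[j] for j in vi],
            samples=[self.samples[i] for i in si],
            dosages=self.dosages[np.ix_(si, vi)],
            phased=self.phased,
            haplotypes=hap,
        )

    def region_index(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of variants inside [start_bp, end_bp] (1-based inclusive)."""
        pos = self.positions
        mask = (self.chroms == chrom) & (pos >= start_bp) & (pos <= end_bp)
        return np.flatnonzero(mask)


def region_span_bp(start_bp: int, end_bp: int) -> int:
    """Length in bp of a 1-based inclusive interval."""
    if end_bp < start_bp:
        raise ValueError("end before start")
    return end_bp - start_bp + 1


# ---------------------------------------------------------------------------
# popmap
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> pd.DataFrame:
    """Read a sample->population TSV with header sample_id, population[, ecotype]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"popmap {path} must have columns sample_id, population; got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"popmap has duplicate sample ids: {dups[:10]}")
    return df


def write_popmap(ds: GenotypeDataset, path: str | Path) -> None:
    rows = [
        {"sample_id": s.id, "population": s.population, "ecotype": s.ecotype or ""}
        for s in ds.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _attach_populations(
    sample_ids: Sequence[str], popmap: pd.DataFrame
) -> list[SampleInfo]:
    table = popmap.set_index("sample_id")
    absent = [s for s in sample_ids if s not in table.index]
    if absent:
        raise ValueError(
            f"samples present in genotype file but absent from popmap: {absent[:10]}"
        )
    extra = [s for s in table.index if s not in set(sample_ids)]
    if extra:
        raise ValueError(f"popmap lists unknown samples: {extra[:10]}")
    out = []
    for sid in sample_ids:
        row = table.loc[sid]
        eco = row.get("ecotype")
        eco = None if (eco is None or (isinstance(eco, float) and np.isnan(eco)) or eco == "") else str(eco)
        out.append(SampleInfo(id=sid, population=str(row["population"]), ecotype=eco))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(
    path: str | Path, split_multiallelic: bool, dedup: bool
) -> tuple[list[str], list[SNPInfo], np.ndarray, bool, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    variants: list[SNPInfo] = []
    dos_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    for var in vcf:
        alts = [a for a in var.ALT if a not in (".", "")]
        if len(alts) != 1:
            if not split_multiallelic:
                raise ValueError(
                    f"multiallelic record at {var.CHROM}:{var.POS} "
                    "(pass split_multiallelic=True to split)"
                )
            alt_set = list(range(1, len(alts) + 1))
        else:
            alt_set = [1]
        gts = var.genotypes  # [a1, a2, phased]
        a1 = np.array([g[0] for g in gts], dtype=np.int16)
        a2 = np.array([g[1] for g in gts], dtype=np.int16)
        phased_here = all(bool(g[2]) for g in gts if len(g) > 2)
        all_phased = all_phased and phased_here
        for k in alt_set:
            vid = var.ID or f"{var.CHROM}_{var.POS}"
            if len(alt_set) > 1:
                vid = f"{vid}_alt{k}"
            variants.append(
                SNPInfo(id=vid, chrom=str(var.CHROM), pos=int(var.POS),
                        ref_allele=str(var.REF), alt_allele=str(alts[k - 1]))
            )
            h1 = np.where(a1 < 0, MISSING, np.where(a1 == k, 1, 0)).astype(np.int8)
            h2 = np.where(a2 < 0, MISSING, np.where(a2 == k, 1, 0)).astype(np.int8)
            both = (h1 != MISSING) & (h2 != MISSING)
            d = np.full(n, MISSING, dtype=np.int8)
            d[both] = (h1 + h2)[both]
            dos_cols.append(d)
            hap = np.empty(2 * n, dtype=np.int8)
            hap[0::2], hap[1::2] = h1, h2
            hap_cols.append(hap)
    if not variants:
        raise ValueError(f"no variants parsed from {path}")
    dosages = np.column_stack(dos_cols)
    haps = np.column_stack(hap_cols)
    variants, dosages, haps = _sort_dedup(
        variants, dosages, haps, dedup, by_alleles=split_multiallelic
    )
    return sample_ids, variants, dosages, all_phased, haps


def _sort_dedup(variants, dosages, haps, dedup, by_alleles=False):
    order = sorted(range(len(variants)), key=lambda j: (variants[j].chrom, variants[j].pos))
    variants = [variants[j] for j in order]
    dosages = dosages[:, order]
    if haps is not None:
        haps = haps[:, order]
    keep, seen = [], set()
    for j, v in enumerate(variants):
        # coordinate-level duplicate detection; split multiallelic siblings
        # stay distinct through their allele pair
        key = (v.chrom, v.pos, v.ref_allele, v.alt_allele) if by_alleles else (v.chrom, v.pos)
        if key in seen:
            if not dedup:
                raise ValueError(
                    f"duplicate variant coordinate {v.chrom}:{v.pos} "
                    "(pass dedup=True to keep the first record)"
                )
            logger.warning("dropping duplicate variant %s at %s:%d", v.id, v.chrom, v.pos)
            continue
        seen.add(key)
        keep.append(j)
    variants = [variants[j] for j in keep]
    dosages = dosages[:, keep]
    if haps is not None:
        haps = haps[:, keep]
    return variants, dosages, haps


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def _read_plink_text(path: str | Path, dedup: bool):
    """Read a PED/MAP pair.  ``path`` is the PED file or the shared prefix.

    Allele coding per SNP: ref = lexicographically smaller observed allele,
    alt = larger; '0' is missing.  PED genotypes are unphased by definition.
    """
    path = Path(path)
    if path.suffix == ".ped":
        ped_path, map_path = path, path.with_suffix(".map")
    else:
        ped_path, map_path = path.with_suffix(".ped"), path.with_suffix(".map")
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    m = len(map_df)
    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object))
    alleles = np.array(allele_rows, dtype=object)  # n x 2m
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]
    variants: list[SNPInfo] = []
    n = len(sample_ids)
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        obs = sorted({x for x in np.concatenate([a1[:, j], a2[:, j]]) if x != "0"})
        if len(obs) > 2:
            raise ValueError(f"SNP {map_df.id[j]} has >2 alleles in PED: {obs}")
        ref = obs[0] if obs else "A"
        alt = obs[1] if len(obs) > 1 else "N"
        variants.append(
            SNPInfo(id=str(map_df.id[j]), chrom=str(map_df.chrom[j]),
                    pos=int(map_df.pos[j]), ref_allele=ref, alt_allele=alt)
        )
        called = (a1[:, j] != "0") & (a2[:, j] != "0")
        dosages[called, j] = (
            (a1[called, j] == alt).astype(np.int8) + (a2[called, j] == alt).astype(np.int8)
        )
    variants, dosages, _ = _sort_dedup(variants, dosages, None, dedup)
    return sample_ids, variants, dosages


def read_genotypes(
    path: str | Path,
    popmap_path: str | Path,
    format: str = "vcf",
    split_multiallelic: bool = False,
    dedup: bool = False,
) -> GenotypeDataset:
    """Read genotypes (+ popmap) into a :class:`GenotypeDataset`.

    ``format`` is ``"vcf"`` (plain or gzipped, via cyvcf2) or
    ``"plink_text"`` (PED/MAP pair).  The phase flag is set iff *every*
    genotype separator in the VCF indicates phase.
    """
    popmap = read_popmap(popmap_path)
    if format == "vcf":
        sample_ids, variants, dosages, phased, haps = _read_vcf(
            path, split_multiallelic, dedup
        )
        samples = _attach_populations(sample_ids, popmap)
        return GenotypeDataset(
            variants=variants, samples=samples, dosages=dosages,
            phased=phased, haplotypes=haps if phased else None,
        )
    if format == "plink_text":
        sample_ids, variants, dosages = _read_plink_text(path, dedup)
        samples = _attach_populations(sample_ids, popmap)
        return GenotypeDataset(variants=variants, samples=samples, dosages=dosages)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'plink_text'")


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as VCF 4.2 text ('|' separators iff phased)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sep = "|" if ds.phased else "/"
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pigpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in ds.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.sample_ids) + "\n")
        for j, v in enumerate(ds.variants):
            gts = []
            for i in range(ds.n_samples):
                if ds.phased:
                    h1, h2 = ds.haplotypes[2 * i, j], ds.haplotypes[2 * i + 1, j]
                    a = "." if h1 == MISSING else str(int(h1))
                    b = "." if h2 == MISSING else str(int(h2))
                else:
                    d = ds.dosages[i, j]
                    if d == MISSING:
                        a = b = "."
                    else:
                        a, b = ("0", "0") if d == 0 else (("0", "1") if d == 1 else ("1", "1"))
                gts.append(f"{a}{sep}{b}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# variant filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-rule removal bookkeeping for :func:`filter_variants`.

    ``removed_maf + removed_callrate - removed_both + kept`` equals the
    input variant count.
    """

    n_input: int
    removed_maf: int
    removed_callrate: int
    removed_both: int
    kept: int
    maf_min: float
    call_rate_min: float

    def __post_init__(self) -> None:
        assert (
            self.removed_maf + self.removed_callrate - self.removed_both + self.kept
            == self.n_input
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def variant_call_rate(ds: GenotypeDataset) -> np.ndarray:
    return (ds.dosages != MISSING).mean(axis=0)


def variant_maf(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP minor-allele frequency over non-missing alleles (0 if no calls)."""
    called = ds.dosages != MISSING
    alt = np.where(called, ds.dosages, 0).sum(axis=0).astype(float)
    tot = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.where(tot > 0, tot, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_variants(
    ds: GenotypeDataset, maf_min: float = 0.05, call_rate_min: float = 0.9
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop SNPs with MAF < ``maf_min`` (strict) or call rate < ``call_rate_min``.

    A SNP whose MAF equals the threshold exactly is kept ("less than" is
    strict).  Both rules are evaluated on every SNP so the report can count
    SNPs failing both.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    maf = variant_maf(ds)
    cr = variant_call_rate(ds)
    fail_maf = maf < maf_min
    fail_cr = cr < call_rate_min
    keep = ~(fail_maf | fail_cr)
    report = FilterReport(
        n_input=ds.n_variants,
        removed_maf=int(fail_maf.sum()),
        removed_callrate=int(fail_cr.sum()),
        removed_both=int((fail_maf & fail_cr).sum()),
        kept=int(keep.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
    )
    if report.kept == 0:
        warnings.warn("no variants survive filtering", UserWarning, stacklevel=2)
    return ds.subset(variant_idx=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive."""

    gene_id: str
    name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 4:
        raise ValueError("gene BED needs >= 4 columns (chrom, start, end, name)")
    df = df.rename(columns=dict(enumerate(["chrom", "start", "end", "gene", "score", "strand"])))
    if "strand" not in df.columns:
        df["strand"] = "."
    out = []
    for _, r in df.iterrows():
        strand = str(r["strand"]) if pd.notna(r["strand"]) else "."
        out.append(
            GeneAnnotation(
                gene_id=str(r["gene"]), name=str(r["gene"]), chrom=str(r["chrom"]),
                start_bp=int(r["start"]) + 1, end_bp=int(r["end"]), strand=strand,
            )
        )
    return out


def read_genes_gff3(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """Read gene records from GFF3 via gffutils (coordinates already 1-based)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for g in db.features_of_type(feature):
        name = g.attributes.get("Name", [g.id])[0]
        out.append(
            GeneAnnotation(
                gene_id=g.id, name=name, chrom=str(g.seqid),
                start_bp=int(g.start), end_bp=int(g.end), strand=g.strand or ".",
            )
        )
    return out
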