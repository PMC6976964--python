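"""End-to-end pipeline: one config drives simulate/load -> filter ->
diversity -> distances/trees -> ROH -> LD -> LSBL -> haplotype analyses,
with a run manifest recording every output and a parameter hash.

Stage order is fixed (dependency order); the ``stages`` list selects which
run.  Reruns with an identical config are byte-identical because every
stage is deterministic given the seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import haplotypes as hap
from . import io as gio
from . import ld as ldmod
from . import phylo, popgen, roh as rohmod, simulate as sim
from .lsbl import run_three_population_scan

logger = logging.getLogger(__name__)

#: The two named three-population scan templates: focal group A vs B and C,
#: as breed lists.  Tibetan contrast = Tibetan (Gansu) pigs against South-
#: and East-Chinese breeds; TEB contrast = two-end-black breeds against
#: solid-black East-Chinese and South/Southwest-Chinese breeds.
TIBETAN_CONTRAST: dict[str, list[str]] = {
    "A": ["Tibetan"],
    "B": ["Bamaxiang", "Congjiangxiang", "Dahuabai", "Dongshanxiang", "Lantang",
          "Luchuan", "Huai", "Tunchang", "Wuzhishan"],
    "C": ["Erhualian", "Jinhua", "Jiangquhai", "Jiaxinghei", "LepingSpotted",
          "Mi", "Putianhei", "Shengxianhua", "Wannanhua", "Yushanhei"],
}
TEB_CONTRAST: dict[str, list[str]] = {
    "A": ["Bamaxiang", "Luchuan", "Dongshanxiang", "Tongcheng", "Shaziling"],
    "B": ["Erhualian", "Jiaxinghei", "Jiangquhai", "Mi", "Shengxianhua"],
    "C": ["Tunchang", "Lantang", "Wuzhishan", "Bamei", "Baoshan", "Dahe",
          "Tibetan", "Mingguang", "Neijiang", "Qingping", "Saba"],
}

STAGE_ORDER = [
    "simulate", "filter", "diversity", "fst", "tree", "roh", "ld",
    "lsbl", "haplotype", "associate",
]


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    out_dir: Path
    seed: int
    stages: list[str]
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    input_genotypes: Path | None = None
    input_popmap: Path | None = None
    input_format: str = "vcf"

    @classmethod
    def from_dict(cls, raw: dict[str, Any], out_dir: str | Path) -> "RunConfig":
        stages = raw.get("stages", [s for s in STAGE_ORDER if s in raw])
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}")
        inp = raw.get("input", {})
        cfg = cls(
            out_dir=Path(out_dir),
            seed=int(raw.get("seed", 0)),
            stages=[s for s in STAGE_ORDER if s in stages],
            params={s: dict(raw.get(s, {})) for s in STAGE_ORDER},
            input_genotypes=Path(inp["genotypes"]) if "genotypes" in inp else None,
            input_popmap=Path(inp["popmap"]) if "popmap" in inp else None,
            input_format=inp.get("format", "vcf"),
        )
        for p in (cfg.input_genotypes, cfg.input_popmap):
            if p is not None and not p.exists():
                raise FileNotFoundError(p)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw, out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {"seed": cfg.seed, "stages": cfg.stages, "params": cfg.params},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest (also written
    to ``manifest.json`` in the output directory)."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    ds: gio.GenotypeDataset | None = None

    def emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.setdefault(stage, []).append(name)

    try:
        for stage in cfg.stages:
            p = cfg.params.get(stage, {})
            if stage == "simulate":
                scfg = sim.SimulationConfig(seed=cfg.seed, **p)
                ds = (
                    sim.simulate_haplotype_region(scfg)
                    if scfg.planted_blocks
                    else sim.simulate_populations(scfg)
                )
                emit(stage, "simulated.vcf", lambda f: gio.write_vcf(ds, f))
                emit(stage, "simulated.popmap.tsv", lambda f: gio.write_popmap(ds, f))
                emit(stage, "truth.json", lambda f: sim.write_truth(scfg, f))
                continue
            if ds is None:
                if cfg.input_genotypes is None:
                    raise ValueError(
                        f"stage {stage!r} needs genotypes: add a simulate stage "
                        "or an input block"
                    )
                ds = gio.read_genotypes(
                    cfg.input_genotypes, cfg.input_popmap, format=cfg.input_format
                )
            if stage == "filter":
                ds, report = gio.filter_variants(ds, **p)
                emit(stage, "filter_report.tsv",
                     lambda f: report.to_frame().to_csv(f, sep="\t", index=False))
            elif stage == "diversity":
                emit(stage, "diversity.tsv",
                     lambda f: popgen.diversity_table(ds).to_csv(f, sep="\t", index=False))
            elif stage == "fst":
                grouping = ds.population_grouping()
                mat = popgen.pairwise_fst_matrix(ds, grouping, **p)
                emit(stage, "fst_matrix.tsv", mat.to_tsv)
            elif stage == "tree":
                grouping = ds.population_grouping()
                mat = popgen.pairwise_fst_matrix(
                    ds, grouping, **cfg.params.get("fst", {})
                )
                tree = phylo.neighbor_joining(mat)
                emit(stage, "breeds.nwk", lambda f: phylo.write_newick(tree, f))
                ibs = popgen.ibs_distance_matrix(ds)
                emit(stage, "ibs_matrix.tsv", ibs.to_tsv)
                if len(ibs.labels) >= 3:
                    itree = phylo.neighbor_joining(ibs)
                    emit(stage, "individuals.nwk", lambda f: phylo.write_newick(itree, f))
            elif stage == "roh":
                segs = rohmod.call_roh(ds, rohmod.ROHParams(**p))
                emit(stage, "roh_segments.tsv",
                     lambda f: rohmod.segments_to_frame(segs).to_csv(f, sep="\t", index=False))
                emit(stage, "roh_summary.tsv",
                     lambda f: rohmod.classify_roh(segs).to_csv(f, sep="\t", index=False))
            elif stage == "ld":
                pops = p.pop("populations", None) or list(ds.populations())
                rows = []
                for popname in pops:
                    pairs = ldmod.compute_ld_pairs(ds, ds.populations()[popname], **p)
                    try:
                        fit = ldmod.fit_decay(pairs)
                        rows.append({"population": popname, "rate_per_kb": fit.rate,
                                     "r03_kb": fit.r03_kb, "n_pairs": len(pairs)})
                    except ValueError as exc:
                        logger.warning("LD fit skipped for %s: %s", popname, exc)
                emit(stage, "ld_decay.tsv",
                     lambda f: pd.DataFrame(rows).to_csv(f, sep="\t", index=False))
            elif stage == "lsbl":
                groups = p.pop("groups")
                members = ds.populations()
                sets = {
                    lab: {sid for b in breeds for sid in members.get(b, [])}
                    for lab, breeds in groups.items()
                }
                res = run_three_population_scan(
                    ds, sets["A"], sets["B"], sets["C"], **p
                )
                emit(stage, "lsbl.tsv",
                     lambda f: res.to_frame(ds.variants).to_csv(f, sep="\t", index=False))
            elif stage == "haplotype":
                region = (p["chrom"], int(p["start_bp"]), int(p["end_bp"]))
                tbl = hap.extract_haplotypes(ds, *region)
                emit(stage, "haplotype_counts.tsv",
                     lambda f: tbl.counts.to_csv(f, sep="\t"))
                emit(stage, "haplotype_sharing.tsv",
                     lambda f: hap.haplotype_sharing_matrix(tbl).to_csv(f, sep="\t"))
                try:
                    net = hap.haplotype_network(tbl, min_count=p.get("min_count", 10))
                    emit(stage, "haplotype_network_edges.tsv",
                         lambda f: pd.DataFrame(
                             net.edges, columns=["hap_a", "hap_b", "n_diff"]
                         ).to_csv(f, sep="\t", index=False))
                    emit(stage, "haplotype_network.graphml", lambda f: _write_graphml(net, f))
                except ValueError as exc:
                    logger.warning("network skipped: %s", exc)
                targets = p.get("target_pops")
                if targets:
                    blocks = hap.shared_fixed_blocks(
                        ds, *region, target_pops=targets,
                        fixation_min=p.get("fixation_min", 0.95),
                    )
                    emit(stage, "shared_blocks.tsv",
                         lambda f: pd.DataFrame(
                             [{"start_bp": b.start_bp, "end_bp": b.end_bp,
                               "n_snps": b.n_snps, "span_bp": b.span_bp,
                               "alleles": b.shared_allele_string} for b in blocks]
                         ).to_csv(f, sep="\t", index=False))
            elif stage == "associate":
                trait = pd.read_csv(p["trait_path"], sep="\t")
                region = (p["chrom"], int(p["start_bp"]), int(p["end_bp"]))
                carrier = hap.haplotype_carrier_status(ds, *region, p["haplotype"])
                trait = trait.set_index("sample_id").loc[ds.sample_ids]
                res = hap.carrier_association(carrier, trait["trait"].to_numpy())
                emit(stage, "association.tsv",
                     lambda f: pd.DataFrame([res.__dict__]).to_csv(f, sep="\t", index=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "stages": cfg.stages,
        "params_hash": _params_hash(cfg),
        "outputs": {
            s: [{"file": f, "sha256": _sha256(out / f)} for f in files]
            for s, files in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_graphml(net, path: Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)
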