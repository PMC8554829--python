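"""Pipeline orchestration: simulate -> filter -> stats -> LD -> burden -> sweep.

One declarative YAML config drives every stage with deterministic seeds; a
machine-readable run manifest records config hash, per-stage output checksums
and wall-clock times.  Any stage run through the pipeline writes byte-identical
output to the same stage run standalone with the same parameters.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import lddecay, popstats, sweepscan
from .errors import ConfigurationError, PopgenError
from .simulate import (OUTGROUP_NAME, SimulationConfig, SweepSpec,
                       simulate_cohort, write_cohort)
from .variantio import (PopulationMap, filter_maf, filter_sites,
                        read_annotation, read_population_map, read_vcf,
                        write_vcf)

log = logging.getLogger(__name__)

VERSION = "0.1.0"

#: analysis defaults; the printed values of the study the pipeline reimplements
DEFAULTS = {
    "filter": {"qual": 30.0, "qd": 2.0, "mq": 30.0, "mq0_dp": 0.1, "maf": None},
    "stats": {"window": 1_000_000, "step": 1_000_000},
    "ld": {"population": None, "max_dist": 300_000, "bin": 1_000, "maf": 0.05},
    "prune": {"window": 50, "step": 5, "r2": 0.5},
    "burden": {"outgroup": OUTGROUP_NAME, "sift": 0.05},
    "sweep": {"focal": None, "background": None, "window": 100_000,
              "step": 10_000, "combine": "all", "z_min": 3.0, "mu_top": 0.05,
              "snp_window": 50},
}

_KNOWN_TOP = {"simulate", "inputs", "outdir", "stages", "filter", "stats",
              "ld", "prune", "burden", "sweep", "seed"}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)    # vcf, popmap, annotation, gff3
    stages: list[str] = field(default_factory=lambda: ["simulate"])
    params: dict = field(default_factory=dict)    # stage -> parameter dict


def _merge(stage: str, overrides: dict) -> dict:
    out = dict(DEFAULTS[stage])
    out.update(overrides or {})
    return out


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, reporting *all* violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown key {key!r}")
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    sim = None
    if "simulate" in raw:
        block = dict(raw["simulate"] or {})
        sweeps = tuple(SweepSpec(**s) for s in block.pop("sweeps", []))
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        for key in block:
            if key not in known:
                errors.append(f"simulate: unknown key {key!r}")
        block = {k: v for k, v in block.items() if k in known}
        for key in ("samples_per_pop", "split_times"):
            if key in block:
                block[key] = tuple(block[key])
        if "bottleneck" in block and block["bottleneck"] is not None:
            block["bottleneck"] = tuple(block["bottleneck"])
        try:
            sim = SimulationConfig(seed=raw.get("seed", 0), **block,
                                   sweeps=sweeps)
            sim.validate()
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulate: {exc}")
    stages = raw.get("stages", ["simulate"] if "simulate" in raw else [])
    known_stages = ("simulate", "filter", "stats", "ld", "prune", "burden",
                    "sweep")
    for s in stages:
        if s not in known_stages:
            errors.append(f"stages: unknown stage {s!r}")
    if "simulate" not in raw and "simulate" in stages:
        errors.append("stage 'simulate' requires a simulate block")
    if "simulate" not in raw and "inputs" not in raw and stages:
        errors.append("either a simulate block or an inputs block is required")
    params = {}
    for stage in ("filter", "stats", "ld", "prune", "burden", "sweep"):
        block = raw.get(stage) or {}
        for key in block:
            if key not in DEFAULTS[stage]:
                errors.append(f"{stage}: unknown key {key!r}")
        params[stage] = _merge(stage, block)
    if "sweep" in stages:
        sw = params["sweep"]
        if not sw["focal"] or not sw["background"]:
            errors.append("sweep: focal and background populations required")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return PipelineConfig(outdir=raw["outdir"], seed=int(raw.get("seed", 0)),
                          simulate=sim, inputs=raw.get("inputs", {}),
                          stages=list(stages), params=params)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict[str, dict]        # stage -> {seconds, outputs: {path: sha256}}
    warnings: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def run(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages; abort on the first stage failure."""
    os.makedirs(config.outdir, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps({
            "seed": config.seed, "stages": config.stages,
            "params": config.params,
            "simulate": None if config.simulate is None else {
                **dataclasses.asdict(config.simulate),
                "sweeps": [dataclasses.asdict(s)
                           for s in config.simulate.sweeps]},
            "inputs": config.inputs,
        }, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(VERSION, cfg_hash, {}, [])

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    table = ann = popmap = None
    pops: dict[str, list[str]] = {}

    def load_inputs():
        nonlocal table, ann, popmap, pops
        table = read_vcf(config.inputs["vcf"])
        popmap = read_population_map(config.inputs["popmap"])
        if "annotation" in config.inputs:
            ann = read_annotation(config.inputs["annotation"])
        pops = {p: popmap.members(p) for p in popmap.populations()}

    genes_df = None
    polarized = classes = None
    div_windows = fst_windows = None

    for stage in config.stages:
        t0 = time.perf_counter()
        outputs: list[str] = []
        try:
            if stage == "simulate":
                table, ann, truth = simulate_cohort(config.simulate)
                paths = write_cohort(table, ann, truth, config.outdir)
                outputs += list(paths.values())
                popmap = PopulationMap(truth.sample_map, outgroup=OUTGROUP_NAME)
                pops = {p: popmap.members(p) for p in popmap.populations()}
                genes_df = truth.genes
            elif stage == "filter":
                if table is None:
                    load_inputs()
                p = config.params["filter"]
                table, report = filter_sites(table, p["qual"], p["qd"],
                                             p["mq"], p["mq0_dp"])
                if p["maf"] is not None:
                    table = filter_maf(table, p["maf"])
                write_vcf(table, out("filtered.vcf"))
                with open(out("filter_report.json"), "w") as fh:
                    json.dump(dataclasses.asdict(report), fh, indent=1)
                outputs += [out("filtered.vcf"), out("filter_report.json")]
            elif stage == "stats":
                if table is None:
                    load_inputs()
                p = config.params["stats"]
                div, fst = popstats.windowed_scan(table, pops, p["window"],
                                                  p["step"])
                popstats.diversity_frame(div).to_csv(
                    out("diversity_windows.tsv"), sep="\t", index=False)
                popstats.fst_frame(fst).to_csv(
                    out("fst_windows.tsv"), sep="\t", index=False)
                inb = [popstats.inbreeding_coefficient(table, s)
                       for ss in pops.values() for s in ss]
                pd.DataFrame([vars(r) for r in inb]).to_csv(
                    out("inbreeding.tsv"), sep="\t", index=False)
                outputs += [out("diversity_windows.tsv"),
                            out("fst_windows.tsv"), out("inbreeding.tsv")]
            elif stage == "ld":
                if table is None:
                    load_inputs()
                p = config.params["ld"]
                names = [p["population"]] if p["population"] else list(pops)
                rows = []
                for name in names:
                    sub = filter_maf(table, p["maf"], samples=pops[name])
                    curve = lddecay.ld_decay_curve(sub, pops[name],
                                                   p["max_dist"], p["bin"])
                    dist, reached = lddecay.half_decay_distance(curve)
                    df = lddecay.curve_frame(curve)
                    df.insert(0, "population", name)
                    rows.append(df)
                    manifest.warnings += ([] if reached else
                                          [f"ld: {name}: half decay not reached"])
                    log.info("ld: %s half-decay %.0f bp (reached=%s)",
                             name, dist, reached)
                pd.concat(rows).to_csv(out("ld_decay.tsv"), sep="\t",
                                       index=False)
                outputs.append(out("ld_decay.tsv"))
            elif stage == "prune":
                if table is None:
                    load_inputs()
                p = config.params["prune"]
                res = lddecay.ld_prune(table, p["window"], p["step"], p["r2"])
                kept = table.take_sites(np.array(res.retained, dtype=int))
                with open(out("pruned_sites.tsv"), "w") as fh:
                    fh.write("chrom\tpos\n")
                    for c, q in zip(kept.chrom, kept.pos):
                        fh.write(f"{c}\t{q}\n")
                thr = lddecay.significance_threshold(len(res.retained))
                with open(out("prune_summary.json"), "w") as fh:
                    json.dump({"retained": len(res.retained),
                               "removed": len(res.removed),
                               "significance_threshold": thr}, fh, indent=1)
                outputs += [out("pruned_sites.tsv"), out("prune_summary.json")]
            elif stage == "burden":
                if table is None:
                    load_inputs()
                if ann is None:
                    raise PopgenError("burden stage requires an annotation")
                p = config.params["burden"]
                polarized = burden_mod.polarize(table, p["outgroup"])
                aligned = ann.aligned_to(table).iloc[polarized.site_index]
                classes = burden_mod.classify_sites(aligned)
                profiles = burden_mod.burden_per_sample(polarized, classes)
                burden_mod.burden_frame(profiles).to_csv(
                    out("burden_profiles.tsv"), sep="\t", index=False)
                sfs = burden_mod.derived_sfs_by_class(polarized, classes)
                burden_mod.sfs_frame(sfs).to_csv(out("sfs_by_class.tsv"),
                                                 sep="\t", index=False)
                pfams = burden_mod.pfam_burden(
                    polarized, classes,
                    aligned["pfam_id"].fillna("").to_numpy())
                pd.DataFrame([vars(p_) for p_ in pfams]).to_csv(
                    out("pfam_burden.tsv"), sep="\t", index=False)
                hf = burden_mod.het_fraction_by_class(polarized, classes)
                with open(out("het_fraction.json"), "w") as fh:
                    json.dump(hf, fh, indent=1)
                outputs += [out("burden_profiles.tsv"), out("sfs_by_class.tsv"),
                            out("pfam_burden.tsv"), out("het_fraction.json")]
            elif stage == "sweep":
                if table is None:
                    load_inputs()
                p = config.params["sweep"]
                focal, background = p["focal"], p["background"]
                div, fst = popstats.windowed_scan(
                    table, {focal: pops[focal], background: pops[background]},
                    p["window"], p["step"])
                f_div = [w for w in div if w.population == focal]
                b_div = [w for w in div if w.population == background]
                ori = None
                if (popmap is not None and popmap.outgroup
                        and popmap.outgroup in table.samples):
                    ori = burden_mod.derived_orientation(table, popmap.outgroup)
                mu = sweepscan.mu_statistic(table, pops[focal],
                                            snp_window=p["snp_window"],
                                            derived_is_alt=ori)
                windows = sweepscan.assemble_sweep_windows(
                    f_div, b_div, fst, mu, mu_top=p["mu_top"])
                regions = sweepscan.candidate_regions(
                    windows, combine=p["combine"], z_min=p["z_min"])
                if genes_df is None and "gff3" in config.inputs:
                    genes_df = sweepscan.read_gff3_genes(config.inputs["gff3"])
                if genes_df is not None:
                    regions = sweepscan.genes_in_regions(regions, genes_df)
                sweepscan.windows_frame(windows).to_csv(
                    out("sweep_windows.tsv"), sep="\t", index=False)
                with open(out("sweep_regions.bed"), "w") as fh:
                    fh.write(sweepscan.regions_bed(regions))
                pd.DataFrame(
                    [{"chrom": r.chrom, "start": r.start, "end": r.end,
                      "gene_id": g} for r in regions for g in r.genes]
                ).to_csv(out("sweep_genes.tsv"), sep="\t", index=False)
                outputs += [out("sweep_windows.tsv"), out("sweep_regions.bed"),
                            out("sweep_genes.tsv")]
        except Exception as exc:
            raise PopgenError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {os.path.basename(o): _sha256(o) for o in outputs},
        }
    manifest.to_json(os.path.join(config.outdir, "manifest.json"))
    return manifest
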