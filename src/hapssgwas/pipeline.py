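"""End-to-end pipeline: simulate -> QC -> block -> encode -> relate -> sample -> associate -> select.

A single YAML config describes either a simulation or real phased
inputs, the QC thresholds, the LD thresholds to block at, the scenario
grid (haplotypes only and/or haplotypes + NCSNP per threshold), the
variance components and chain settings, and the top-selection level.
Outputs are plain TSV/JSON files per scenario plus a run manifest;
identical config and seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simdata, qc as qcmod, haploblock, pseudosnp, relmat, liabmodel, assoc, topselect

log = logging.getLogger("hapssgwas")


@dataclass
class SimConfig:
    n_founders: int = 120
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_markers_per_chr: int = 150
    n_chr: int = 3
    adjacent_r2_target: float = 0.6
    spacing_bp: int = 50_000
    maf_floor: float = 0.05
    recomb_rate_per_bp: float = 1e-8
    genotyped_fraction: float = 0.5
    call_rate: float = 0.99


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    base_seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    trait: simdata.TraitSimSpec = field(default_factory=simdata.TraitSimSpec)
    qc: qcmod.QcThresholds = field(default_factory=qcmod.QcThresholds)
    ld_thresholds: tuple = (0.15, 0.50, 0.80)
    include_ncsnp: tuple = (False, True)
    varcomps: liabmodel.VarianceComponents = field(
        default_factory=lambda: liabmodel.VarianceComponents(0.10, 0.38, 0.52))
    gibbs: liabmodel.GibbsConfig = field(default_factory=liabmodel.GibbsConfig)
    hinv: relmat.HInverseConfig = field(default_factory=relmat.HInverseConfig)
    n_weight_iters: int = 3
    top_level: float = topselect.TOP_LEVEL_DEFAULT
    scan_window_markers: int = 50
    min_pair_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "sim" in kw:
            kw["sim"] = SimConfig(**kw["sim"])
        if "trait" in kw:
            kw["trait"] = simdata.TraitSimSpec(**kw["trait"])
        if "qc" in kw:
            kw["qc"] = qcmod.QcThresholds(**kw["qc"])
        if "varcomps" in kw:
            kw["varcomps"] = liabmodel.VarianceComponents(**kw["varcomps"])
        if "gibbs" in kw:
            kw["gibbs"] = liabmodel.GibbsConfig(**kw["gibbs"])
        if "hinv" in kw:
            kw["hinv"] = relmat.HInverseConfig(**kw["hinv"])
        for t in ("ld_thresholds", "include_ncsnp"):
            if t in kw:
                kw[t] = tuple(kw[t])
        return cls(**kw)


def scenario_label(ld_threshold: float, include_ncsnp: bool) -> str:
    base = f"H{ld_threshold:.2f}"
    return f"NCSNP_{base}" if include_ncsnp else base


def simulate_study(cfg: PipelineConfig):
    """Generate pedigree, genotypes and phenotypes per the config."""
    s = cfg.sim
    seed = cfg.base_seed
    ped = simdata.simulate_pedigree(s.n_founders, s.n_generations,
                                    s.offspring_per_mating, seed=seed)
    decay = simdata.decay_rate_for_adjacent_r2(s.adjacent_r2_target, s.spacing_bp)
    mmap, founders = simdata.simulate_founder_haplotypes(
        s.n_markers_per_chr, s.n_chr, decay, s.maf_floor,
        seed=seed + 1, n_individuals=s.n_founders, spacing_bp=s.spacing_bp)
    geno = simdata.gene_drop(ped, founders, s.recomb_rate_per_bp, seed=seed + 2)
    trait = simdata.TraitSimSpec(**{**asdict(cfg.trait), "seed": seed + 3})
    pheno = simdata.simulate_phenotypes(geno, ped, trait)
    masked, genotyped_ids = simdata.mask_data(
        geno, s.genotyped_fraction, s.call_rate, seed=seed + 4)
    return ped, masked, pheno, genotyped_ids


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full scenario grid; returns a summary dict (also on disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, geno, pheno, genotyped_ids = simulate_study(cfg)
    log.info("simulated %d animals (%d genotyped), %d markers",
             len(ped), len(genotyped_ids), len(geno.markers))

    # SNP-level QC on the genotyped subset
    sub = geno.subset_individuals(genotyped_ids)
    dosages = sub.dosages()
    d_qc, surv_animals, keep_cols, report = qcmod.run_qc(
        dosages, genotyped_ids, geno.markers, cfg.qc)
    report.to_json(out / "qc_report.json")
    sub = sub.subset_individuals(surv_animals).subset_markers(keep_cols)

    ped.to_frame().to_csv(out / "pedigree.csv", index=False)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    simdata.write_vcf(out / "genotypes.vcf", sub)
    simdata.write_marker_map(out / "marker_map.tsv", sub.markers)

    A = relmat.build_A(ped)
    spec = liabmodel.ThresholdModelSpec()
    design = liabmodel.build_design(pheno, spec, list(ped.ids))
    sdata = assoc.ScenarioData(pedigree=ped, design=design,
                               varcomps=cfg.varcomps, gibbs=cfg.gibbs,
                               hinv=cfg.hinv, A=A)

    summary = {"scenarios": {}, "block_stats": {}}
    selections = {}
    for thr in cfg.ld_thresholds:
        bcfg = haploblock.BlockingConfig(ld_threshold=thr,
                                         scan_window_markers=cfg.scan_window_markers,
                                         min_pair_fraction=cfg.min_pair_fraction)
        blocks, ncsnp = haploblock.build_blocks_genome(sub, bcfg)
        stats = haploblock.block_stats(blocks, ncsnp, sub.markers)
        summary["block_stats"][f"{thr:.2f}"] = stats
        haploblock.write_blocks_bed(out / f"blocks_H{thr:.2f}.bed", blocks, sub.markers)
        (out / f"ncsnp_H{thr:.2f}.txt").write_text("\n".join(ncsnp) + "\n" if ncsnp else "")
        for inc in cfg.include_ncsnp:
            label = scenario_label(thr, inc)
            mm = pseudosnp.assemble_matrix(sub, blocks, ncsnp, include_ncsnp=inc,
                                           qc=cfg.qc)
            results = assoc.run_scenario(sdata, mm, label,
                                         n_weight_iters=cfg.n_weight_iters)
            sdir = out / label
            sdir.mkdir(exist_ok=True)
            scen = {}
            for res in results:
                res.effects.to_csv(sdir / f"effects_iter{res.iteration}.tsv",
                                   sep="\t", index=False)
                res.block_variance.to_csv(
                    sdir / f"block_variance_iter{res.iteration}.tsv",
                    sep="\t", index=False)
                res.gebv.to_csv(sdir / f"gebv_iter{res.iteration}.tsv",
                                sep="\t", index=False)
                vem = res.effects["vem_pct"].to_numpy()
                pos_vals = vem[vem > 0]
                top = None
                if len(np.unique(pos_vals)) >= 4 and pos_vals.std() > 0:
                    fam = topselect.choose_family_likelihood(pos_vals)
                    try:
                        fit = topselect.fit_distribution(pos_vals, fam)
                    except (ValueError, RuntimeError):
                        fam = "gamma"
                        fit = topselect.fit_distribution(pos_vals, fam)
                    top = topselect.select_top(vem, fit, cfg.top_level,
                                               meta=res.effects)
                if top is not None:
                    top.selected.to_csv(sdir / f"top_iter{res.iteration}.tsv",
                                        sep="\t", index=False)
                    scen[f"iter{res.iteration}"] = {
                        "n_top": int(len(top.selected)),
                        "threshold": top.threshold,
                    }
                    if res.iteration == 1:
                        selections[label] = top.selected
            summary["scenarios"][label] = scen

    if len(selections) > 1:
        topselect.overlap_report(selections).to_csv(out / "overlap.csv", index=False)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest(),
        "base_seed": cfg.base_seed,
        "n_animals": len(ped),
        "n_genotyped": len(genotyped_ids),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump({**manifest, **summary}, fh, indent=1, default=str)
    return summary


def summarize_blocks(run_dir) -> pd.DataFrame:
    """Assemble the per-threshold block descriptive table from a run dir."""
    with open(Path(run_dir) / "manifest.json") as fh:
        man = json.load(fh)
    rows = []
    for thr, st in man.get("block_stats", {}).items():
        rows.append({"ld_threshold": thr, **st})
    return pd.DataFrame(rows)
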