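"""Study-scale simulation experiments used for validation.

These functions reproduce, at desk scale, the properties the method is
expected to show on real data: stability of GEBVs across nonlinear-A
weighting iterations, the two-SNP minimum block size, and localization
of a moderate QTL to its haploblock.  They are deliberately
self-contained (simulate -> run -> measure) so they can be driven both
from the test suite and from reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simdata as sd
from . import haploblock as hb
from . import pseudosnp as ps
from . import assoc, liabmodel as lm, relmat


@dataclass
class StudyPopulation:
    pedigree: sd.Pedigree
    genotypes: sd.PhasedGenotypes       # masked
    phenotypes: object                  # DataFrame
    genotyped_ids: list[str]


def simulate_population(seed: int, n_founders: int = 250, n_generations: int = 3,
                        offspring_per_mating: int = 3,
                        n_markers_per_chr: int = 500, n_chr: int = 3,
                        adjacent_r2: float = 0.6, spacing_bp: int = 50_000,
                        genotyped_fraction: float = 0.5, call_rate: float = 0.99,
                        n_qtl: int = 300, h2: float = 0.38,
                        true_bv: np.ndarray | None = None,
                        genotypes_hook=None) -> StudyPopulation:
    """Polygenic 4-category study population (~2,000 animals by default).

    ``genotypes_hook(ped, geno)`` may compute a custom true breeding
    value from the dropped genotypes (e.g., to place a focal QTL).
    """
    ped = sd.simulate_pedigree(n_founders, n_generations, offspring_per_mating,
                               seed=seed)
    decay = sd.decay_rate_for_adjacent_r2(adjacent_r2, spacing_bp)
    _, founders = sd.simulate_founder_haplotypes(
        n_markers_per_chr, n_chr, decay, maf_floor=0.05, seed=seed + 10_000,
        n_individuals=n_founders, spacing_bp=spacing_bp)
    geno = sd.gene_drop(ped, founders, recomb_rate_per_bp=1e-8, seed=seed + 20_000)
    if genotypes_hook is not None:
        true_bv = genotypes_hook(ped, geno)
    spec = sd.TraitSimSpec(n_qtl=n_qtl, h2=h2, seed=seed + 30_000)
    pheno = sd.simulate_phenotypes(geno, ped, spec, true_bv=true_bv)
    masked, genotyped_ids = sd.mask_data(geno, genotyped_fraction, call_rate,
                                         seed=seed + 40_000)
    return StudyPopulation(ped, masked, pheno, genotyped_ids)


def _scenario_inputs(pop: StudyPopulation, ld_threshold: float,
                     include_ncsnp: bool):
    sub = pop.genotypes.subset_individuals(pop.genotyped_ids)
    cfg = hb.BlockingConfig(ld_threshold=ld_threshold)
    blocks, ncsnp = hb.build_blocks_genome(sub, cfg)
    mm = ps.assemble_matrix(sub, blocks, ncsnp, include_ncsnp=include_ncsnp)
    return sub, blocks, ncsnp, mm


def gebv_stability(seed: int, ld_threshold: float = 0.50,
                   gibbs: lm.GibbsConfig | None = None,
                   **pop_kwargs) -> float:
    """Pearson correlation of genotyped-animal GEBVs between the
    unweighted analysis and the first nonlinear-A weighted iteration."""
    pop = simulate_population(seed, **pop_kwargs)
    _, _, _, mm = _scenario_inputs(pop, ld_threshold, include_ncsnp=False)
    design = lm.build_design(pop.phenotypes, lm.ThresholdModelSpec(),
                             list(pop.pedigree.ids))
    vc = lm.VarianceComponents(sigma2_w=0.10, sigma2_g=0.38, sigma2_e=0.52)
    gibbs = gibbs or lm.GibbsConfig(seed=seed)
    data = assoc.ScenarioData(pedigree=pop.pedigree, design=design,
                              varcomps=vc, gibbs=gibbs)
    res = assoc.run_scenario(data, mm, f"H{ld_threshold:.2f}", n_weight_iters=2)
    idx = pop.pedigree.index
    gi = np.array([idx[a] for a in mm.ids])
    u1 = res[0].gebv["gebv"].to_numpy()[gi]
    u2 = res[1].gebv["gebv"].to_numpy()[gi]
    return float(np.corrcoef(u1, u2)[0, 1])


def min_block_sizes(seed: int, thresholds=(0.15, 0.50, 0.80),
                    n_markers: int = 200, n_individuals: int = 400,
                    adjacent_r2: float = 0.9, spacing_bp: int = 50_000) -> dict:
    """Minimum SNPs-per-block at each LD threshold on one simulated
    chromosome whose adjacent-pair LD exceeds all the thresholds."""
    decay = sd.decay_rate_for_adjacent_r2(adjacent_r2, spacing_bp)
    _, geno = sd.simulate_founder_haplotypes(
        n_markers, 1, decay, maf_floor=0.1, seed=seed,
        n_individuals=n_individuals, spacing_bp=spacing_bp)
    out = {}
    for thr in thresholds:
        cfg = hb.BlockingConfig(ld_threshold=thr)
        blocks, _ = hb.build_blocks_genome(geno, cfg)
        out[thr] = min(b.n_snps for b in blocks) if blocks else 0
    return out


def qtl_localization(seed: int, qtl_share: float = 0.05,
                     ld_threshold: float = 0.50,
                     gibbs: lm.GibbsConfig | None = None,
                     top_level: float = 1e-5,
                     **pop_kwargs) -> dict:
    """Place one QTL carrying ``qtl_share`` of the genetic variance inside
    a haploblock and check the block tops the VEH% ranking.

    Returns the focal block id, whether it attains the maximum VEH%, and
    whether it exceeds the fitted upper-tail selection threshold.
    """
    from . import topselect as tsel

    pop_kwargs.setdefault("n_founders", 150)
    pop_kwargs.setdefault("offspring_per_mating", 3)
    pop_kwargs.setdefault("n_markers_per_chr", 250)
    pop_kwargs.setdefault("n_chr", 2)
    state = {}

    def hook(ped, geno):
        # block the TRUE (unmasked) haplotypes to find a focal block
        rng = np.random.default_rng(seed + 77)
        blocks, _ = hb.build_blocks_genome(geno, hb.BlockingConfig(ld_threshold=ld_threshold))
        blocks = [b for b in blocks if b.n_snps >= 2]
        focal = blocks[rng.integers(0, len(blocks))]
        # use a marker in the middle of the block as the causal variant
        focal_marker = focal.marker_ids[len(focal.marker_ids) // 2]
        mm_frame = geno.markers.frame
        focal_col = mm_frame.index[mm_frame["marker_id"] == focal_marker][0]
        state["focal_marker"] = focal_marker
        dos = geno.dosages()
        m = dos.shape[1]
        bg_idx = rng.choice([j for j in range(m) if j != focal_col],
                            size=300, replace=False)
        bg_eff = rng.normal(size=300)
        bg = dos[:, bg_idx] @ bg_eff
        bg = (bg - bg.mean())
        bg *= np.sqrt(1.0 - qtl_share) / max(bg.std(), 1e-12)
        fq = dos[:, focal_col] - dos[:, focal_col].mean()
        fq *= np.sqrt(qtl_share) / max(fq.std(), 1e-12)
        order = {a: i for i, a in enumerate(geno.ids)}
        rows = np.array([order[a] for a in ped.ids])
        return (bg + fq)[rows]

    pop = simulate_population(seed, genotypes_hook=hook, **pop_kwargs)
    _, blocks, ncsnp, mm = _scenario_inputs(pop, ld_threshold, include_ncsnp=False)
    design = lm.build_design(pop.phenotypes, lm.ThresholdModelSpec(),
                             list(pop.pedigree.ids))
    vc = lm.VarianceComponents(sigma2_w=0.10, sigma2_g=0.38, sigma2_e=0.52)
    gibbs = gibbs or lm.GibbsConfig(seed=seed)
    data = assoc.ScenarioData(pedigree=pop.pedigree, design=design,
                              varcomps=vc, gibbs=gibbs)
    res = assoc.run_scenario(data, mm, f"H{ld_threshold:.2f}", n_weight_iters=1)[0]
    bv = res.block_variance
    blocks_only = bv[bv["kind"] == "block"]
    top_block = blocks_only.loc[blocks_only["veh_pct"].idxmax(), "block_id"]
    # the scenario re-blocks the genotyped subset: find the block that
    # contains the causal marker there
    focal_marker = state["focal_marker"]
    focal = next((b.block_id for b in blocks if focal_marker in b.marker_ids), None)
    focal_rows = blocks_only[blocks_only["block_id"] == focal]
    focal_veh = float(focal_rows["veh_pct"].iloc[0]) if len(focal_rows) else 0.0

    veh = blocks_only["veh_pct"].to_numpy()
    pos_vals = veh[veh > 0]
    in_top = False
    if len(np.unique(pos_vals)) >= 4:
        fam = tsel.choose_family_likelihood(pos_vals)
        try:
            fit = tsel.fit_distribution(pos_vals, fam)
        except (ValueError, RuntimeError):
            fit = tsel.fit_distribution(pos_vals, "gamma")
        sel = tsel.select_top(veh, fit, top_level)
        in_top = focal_veh > sel.threshold
    return {"focal_block": focal, "top_block": top_block,
            "is_max": top_block == focal, "in_top_selection": in_top,
            "focal_veh_pct": focal_veh}
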