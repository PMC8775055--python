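import numpy as np
import pandas as pd
import pytest

from hapssgwas import simdata as sd


@pytest.fixture(scope="session")
def small_population():
    """~230-animal pedigree with genotypes and phenotypes, shared read-only."""
    ped = sd.simulate_pedigree(60, 3, 2, seed=3)
    decay = sd.decay_rate_for_adjacent_r2(0.7, 50_000)
    _, founders = sd.simulate_founder_haplotypes(
        100, 2, decay, maf_floor=0.05, seed=1, n_individuals=60)
    geno = sd.gene_drop(ped, founders, 1e-8, seed=2)
    spec = sd.TraitSimSpec(n_qtl=50, seed=5,
                           category_probs=(0.6, 0.25, 0.10, 0.05))
    pheno = sd.simulate_phenotypes(geno, ped, spec)
    masked, genotyped_ids = sd.mask_data(geno, 0.6, 0.99, seed=7)
    return {"pedigree": ped, "genotypes": masked, "phenotypes": pheno,
            "genotyped_ids": genotyped_ids, "true": geno}


def toy_phased(hap_strings_a, hap_strings_b, chrom=1, spacing=100):
    """Build a PhasedGenotypes from per-individual allele strings."""
    n = len(hap_strings_a)
    m = len(hap_strings_a[0])
    mm = sd.MarkerMap(pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(m)],
        "chrom": chrom,
        "pos": [spacing * (j + 1) for j in range(m)],
    }))
    def parse(strings):
        out = np.empty((n, m), dtype=np.int8)
        for i, s in enumerate(strings):
            for j, ch in enumerate(s):
                out[i, j] = sd.MISSING if ch == "." else int(ch)
        return out
    return sd.PhasedGenotypes([f"ind{i}" for i in range(n)], mm,
                              parse(hap_strings_a), parse(hap_strings_b))
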