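import numpy as np
import pandas as pd
import pytest

from hapssgwas import simdata as sd
from hapssgwas.haploblock import pairwise_r2


class TestSimulatePedigree:
    def test_founders_only(self):
        ped = sd.simulate_pedigree(10, 0, 2, seed=1)
        assert len(ped) == 10
        assert np.all(ped.sire == -1) and np.all(ped.dam == -1)

    def test_one_generation_parents_are_founders(self):
        ped = sd.simulate_pedigree(4, 1, 2, seed=7)
        for i in range(4, len(ped)):
            assert ped.sire[i] < 4 and ped.dam[i] < 4
            assert ped.sire[i] >= 0 and ped.dam[i] >= 0

    def test_total_count_matches_mating_schedule(self):
        """Cohort sizes follow min(males, females) x offspring_per_mating."""
        ped = sd.simulate_pedigree(20, 3, 2, seed=3)
        gen = np.array([int(a.split("_")[0][1:]) for a in ped.ids])
        expected = 20
        for g in range(1, 4):
            prev = np.where(gen == g - 1)[0]
            males = sum(1 for i in prev if ped.sex[i] == 0)
            females = len(prev) - males
            expected += min(males, females) * 2
        assert len(ped) == expected

    def test_infeasible_mating_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            sd.simulate_pedigree(1, 1, 2, seed=0)

    def test_parents_precede_offspring(self):
        ped = sd.simulate_pedigree(12, 4, 3, seed=9)
        for i in range(len(ped)):
            assert ped.sire[i] < i and ped.dam[i] < i


class TestFounderHaplotypes:
    def test_independence_limit(self):
        _, geno = sd.simulate_founder_haplotypes(
            40, 1, np.inf, 0.1, seed=1, n_individuals=500)
        pairs = pairwise_r2(geno, 1, scan_window_markers=5)
        assert np.mean([p.r2 for p in pairs]) < 0.01

    def test_perfect_copying_limit(self):
        _, geno = sd.simulate_founder_haplotypes(
            30, 1, 0.0, 0.1, seed=2, n_individuals=200)
        hap = np.vstack([geno.hapA, geno.hapB])
        freqs = hap.mean(axis=0)
        # markers sharing an allele frequency run are identical columns
        same = [
            (i, i + 1) for i in range(29) if freqs[i] == freqs[i + 1]
        ]
        assert same, "expected at least one equal-frequency adjacent pair"
        for i, j in same:
            assert np.array_equal(hap[:, i], hap[:, j])

    def test_adjacent_r2_calibration(self):
        """Mean adjacent r2 lands near the decay-implied target."""
        target = 0.6
        decay = sd.decay_rate_for_adjacent_r2(target, 50_000)
        _, geno = sd.simulate_founder_haplotypes(
            200, 1, decay, 0.2, seed=5, n_individuals=1000,
            freq_run_len=1e9)  # one frequency per chromosome
        r2 = [p.r2 for p in pairwise_r2(geno, 1, 2)]
        assert abs(np.mean(r2) - target) < 0.1

    def test_too_few_markers_raises(self):
        with pytest.raises(ValueError, match="2 markers"):
            sd.simulate_founder_haplotypes(1, 1, 0.1, 0.1, seed=0)


class TestGeneDrop:
    def test_no_recombination_copies_a_parental_haplotype(self):
        ped = sd.simulate_pedigree(4, 1, 2, seed=1)
        _, founders = sd.simulate_founder_haplotypes(
            20, 2, 1e-5, 0.1, seed=2, n_individuals=4)
        geno = sd.gene_drop(ped, founders, recomb_rate_per_bp=0.0, seed=3)
        chroms = geno.markers.chroms
        for i in range(4, len(ped)):
            s = ped.sire[i]
            for c in np.unique(chroms):
                sel = chroms == c
                assert (np.array_equal(geno.hapA[i, sel], geno.hapA[s, sel])
                        or np.array_equal(geno.hapA[i, sel], geno.hapB[s, sel]))

    def test_mendelian_consistency(self, small_population):
        geno = small_population["true"]
        ped = small_population["pedigree"]
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            ok_s = (geno.hapA[i] == geno.hapA[s]) | (geno.hapA[i] == geno.hapB[s])
            ok_d = (geno.hapB[i] == geno.hapA[d]) | (geno.hapB[i] == geno.hapB[d])
            assert ok_s.all() and ok_d.all()

    def test_single_known_parent_raises(self):
        ped = sd.simulate_pedigree(2, 0, 1, seed=0)
        bad = sd.Pedigree(ped.ids + ["x"], np.array([-1, -1, 0]),
                          np.array([-1, -1, -1]))
        _, founders = sd.simulate_founder_haplotypes(
            5, 1, 0.1, 0.1, seed=1, n_individuals=2)
        with pytest.raises(ValueError, match="exactly one known parent"):
            sd.gene_drop(bad, founders, 1e-8, seed=2)

    def test_crossover_rate_calibration(self):
        """Observed switch count per gamete matches the Poisson mean."""
        from hapssgwas.simdata import _gamete, MarkerMap
        mm = MarkerMap(pd.DataFrame({
            "marker_id": [f"m{j}" for j in range(200)],
            "chrom": 1, "pos": 50_000 * (1 + np.arange(200))}))
        span = float(mm.positions[-1] - mm.positions[0])
        rate = 2.0 / span
        hapA = np.zeros(200, dtype=np.int8)
        hapB = np.ones(200, dtype=np.int8)
        rng = np.random.default_rng(11)
        switches = []
        for _ in range(1000):
            g = _gamete(hapA, hapB, mm, rate, rng)
            switches.append(int(np.sum(np.abs(np.diff(g.astype(int))))))
        assert abs(np.mean(switches) - 2.0) < 0.2


class TestPhenotypes:
    def test_category_frequencies_match_targets(self):
        """Realized frequencies of the 4 scores track the very unbalanced
        target within binomial error at n = 20,000."""
        n = 20_000
        ped = sd.simulate_pedigree(n, 0, 1, seed=1)
        _, geno = sd.simulate_founder_haplotypes(
            40, 1, 1e-5, 0.1, seed=2, n_individuals=n)
        probs = (0.719, 0.222, 0.051, 0.008)
        spec = sd.TraitSimSpec(n_qtl=20, category_probs=probs, seed=3)
        ph = sd.simulate_phenotypes(geno, ped, spec)
        freq = ph["score"].value_counts(normalize=True).sort_index().to_numpy()
        for f, p in zip(freq, probs):
            tol = 4 * np.sqrt(p * (1 - p) / n)
            assert abs(f - p) < tol, (f, p, tol)

    def test_high_heritability_limit(self):
        """As h2 -> 1 the liability collapses onto the genetic value and
        the observed score becomes a monotone step function of it."""
        ped = sd.simulate_pedigree(2000, 0, 1, seed=4)
        _, geno = sd.simulate_founder_haplotypes(
            10, 1, 1e-5, 0.3, seed=5, n_individuals=2000)
        spec = sd.TraitSimSpec(n_qtl=10, h2=0.999, cg_var_fraction=0.0005,
                               covariate_effect_sd=0.0, age_dev_slope=0.0,
                               seed=6)
        ph = sd.simulate_phenotypes(geno, ped, spec)
        # scores are always a monotone step function of the liability ...
        by_liab = ph.sort_values("true_liability")["score"].to_numpy()
        assert np.all(np.diff(by_liab) >= 0)
        # ... and the liability is essentially the genetic value here
        r = np.corrcoef(ph["true_bv"], ph["true_liability"])[0, 1]
        assert r > 0.999

    def test_null_heritability_gives_zero_genetic_values(self):
        ped = sd.simulate_pedigree(100, 0, 1, seed=7)
        _, geno = sd.simulate_founder_haplotypes(
            10, 1, 0.1, 0.1, seed=8, n_individuals=100)
        spec = sd.TraitSimSpec(h2=0.0, seed=9)
        ph = sd.simulate_phenotypes(geno, ped, spec)
        assert np.all(ph["true_bv"] == 0)

    def test_zero_category_prob_raises(self):
        with pytest.raises(ValueError, match="positive"):
            sd.TraitSimSpec(category_probs=(0.7, 0.3, 0.0, 0.0))

    def test_realized_heritability(self):
        """Regression of liability on true BV recovers h2."""
        n = 10_000
        ped = sd.simulate_pedigree(n, 0, 1, seed=10)
        _, geno = sd.simulate_founder_haplotypes(
            60, 1, 1e-5, 0.1, seed=11, n_individuals=n)
        spec = sd.TraitSimSpec(n_qtl=30, h2=0.38, covariate_effect_sd=0.0,
                               age_dev_slope=0.0, cg_var_fraction=0.10, seed=12)
        ph = sd.simulate_phenotypes(geno, ped, spec)
        bv = ph["true_bv"].to_numpy()
        resid = ph["true_liability"].to_numpy() - bv
        h2_hat = bv.var() / (bv.var() + resid.var())
        assert abs(h2_hat - 0.38) < 0.03


class TestMaskData:
    def test_identity(self, small_population):
        geno = small_population["true"]
        out, ids = sd.mask_data(geno, 1.0, 1.0, seed=1)
        assert ids == geno.ids
        assert np.array_equal(out.hapA, geno.hapA)

    def test_genotyped_count_and_reproducibility(self):
        ped = sd.simulate_pedigree(1000, 0, 1, seed=1)
        _, geno = sd.simulate_founder_haplotypes(
            5, 1, 0.1, 0.1, seed=2, n_individuals=1000)
        _, ids1 = sd.mask_data(geno, 0.5, 1.0, seed=3)
        _, ids2 = sd.mask_data(geno, 0.5, 1.0, seed=3)
        assert len(ids1) == 500
        assert ids1 == ids2

    def test_call_rate_calibration(self):
        ped = sd.simulate_pedigree(200, 0, 1, seed=4)
        _, geno = sd.simulate_founder_haplotypes(
            500, 1, 0.1, 0.1, seed=5, n_individuals=200)
        masked, ids = sd.mask_data(geno, 1.0, 0.8, seed=6)
        cr = (masked.hapA != sd.MISSING).mean(axis=1)
        assert abs(cr.mean() - 0.8) < 0.02


def test_vcf_round_trip(tmp_path, small_population):
    geno = small_population["genotypes"]
    path = tmp_path / "g.vcf"
    sd.write_vcf(path, geno)
    back = sd.read_vcf(path)
    assert back.ids == geno.ids
    assert np.array_equal(back.hapA, geno.hapA)
    assert np.array_equal(back.hapB, geno.hapB)
    assert back.markers.frame.equals(
        geno.markers.frame[["marker_id", "chrom", "pos"]])
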