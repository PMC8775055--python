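import numpy as np
import pandas as pd
import pytest

from hapssgwas import relmat
from hapssgwas import simdata as sd
from hapssgwas.pseudosnp import MarkerMatrix


def ped_from_tuples(records):
    ids = [r[0] for r in records]
    idx = {a: i for i, a in enumerate(ids)}
    sire = np.array([idx.get(r[1], -1) for r in records])
    dam = np.array([idx.get(r[2], -1) for r in records])
    return sd.Pedigree(ids, sire, dam)


def kinship_oracle(ped):
    """Recursive coefficient-of-kinship oracle; A = 2 * kinship."""
    n = len(ped)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            s, d = ped.sire[i], ped.dam[i]
            return 0.5 * (1.0 + f(s, d))
        if j > i:
            i, j = j, i
        # i is the younger: recurse on its parents
        s, d = ped.sire[i], ped.dam[i]
        return 0.5 * (f(s, j) + f(d, j))

    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2.0 * f(i, j)
    return A


def random_pedigree(rng, n):
    records = []
    for i in range(n):
        if i < 2 or rng.uniform() < 0.3:
            records.append((f"a{i}", None, None))
        else:
            s, d = rng.choice(i, 2, replace=False)
            records.append((f"a{i}", f"a{s}", f"a{d}"))
    return ped_from_tuples(records)


def toy_matrix(ids, dosages, p=None):
    dosages = np.asarray(dosages, float)
    m = dosages.shape[1]
    obs = ~np.isnan(dosages)
    if p is None:
        p = np.nansum(dosages, axis=0) / (2 * obs.sum(axis=0))
    meta = pd.DataFrame({
        "col_id": [f"c{j}" for j in range(m)], "source": "ncsnp",
        "block_id": "", "chrom": 1, "pos": 10 * (1 + np.arange(m)),
        "p": p, "weight": 1.0})
    return MarkerMatrix(ids, dosages, meta)


class TestBuildA:
    def test_unrelated_founders_identity(self):
        ped = ped_from_tuples([("a", None, None), ("b", None, None)])
        assert np.array_equal(relmat.build_A(ped), np.eye(2))

    def test_parent_offspring(self):
        ped = ped_from_tuples([("s", None, None), ("d", None, None),
                               ("o", "s", "d")])
        A = relmat.build_A(ped)
        assert A[2, 0] == 0.5 and A[2, 2] == 1.0

    def test_full_sibs(self):
        ped = ped_from_tuples([("s", None, None), ("d", None, None),
                               ("o1", "s", "d"), ("o2", "s", "d")])
        A = relmat.build_A(ped)
        assert A[2, 3] == 0.5

    def test_inbreeding_from_full_sib_mating(self):
        ped = ped_from_tuples([("s", None, None), ("d", None, None),
                               ("o1", "s", "d"), ("o2", "s", "d"),
                               ("x", "o1", "o2")])
        A = relmat.build_A(ped)
        assert A[4, 4] == pytest.approx(1.25)  # F = 0.25

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_kinship_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, int(rng.integers(3, 13)))
        assert np.allclose(relmat.build_A(ped), kinship_oracle(ped), atol=1e-12)

    def test_order_violation_raises(self):
        with pytest.raises(ValueError, match="order"):
            sd.Pedigree(["a", "b"], np.array([1, -1]), np.array([-1, -1]))


class TestBuildG:
    def test_two_animal_hand_example(self):
        mm = toy_matrix(["a", "b"], [[0.0], [2.0]])
        G = relmat.build_G(mm)
        assert mm.k == pytest.approx(0.5)
        assert np.allclose(G, [[2, -2], [-2, 2]])

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        mm = toy_matrix([f"a{i}" for i in range(12)],
                        rng.binomial(2, 0.4, (12, 30)))
        assert np.allclose(relmat.build_G(mm).sum(axis=1), 0, atol=1e-10)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(2)
        mm = toy_matrix([f"a{i}" for i in range(6)],
                        rng.binomial(2, 0.4, (6, 10)))
        G1 = relmat.build_G(mm)
        G2 = relmat.build_G(mm, weights=2 * np.ones(10))
        assert np.allclose(G2, 2 * G1)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        mm = toy_matrix([f"a{i}" for i in range(15)],
                        rng.binomial(2, 0.3, (15, 40)))
        w = np.linalg.eigvalsh(relmat.build_G(mm))
        assert w.min() > -1e-10

    def test_missing_mean_imputed(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 1.0]])
        mm = toy_matrix(["a", "b", "c"], d)
        G = relmat.build_G(mm)  # must not produce NaN
        assert np.isfinite(G).all()


class TestBuildHinv:
    def test_no_genotyped_animals_gives_Ainv(self):
        ped = ped_from_tuples([("a", None, None), ("b", None, None),
                               ("c", "a", "b")])
        A = relmat.build_A(ped)
        Hinv = relmat.build_Hinv(A, np.array([], dtype=int), np.empty((0, 0)))
        assert np.allclose(Hinv, np.linalg.inv(A))

    def test_correction_cancels_when_G_equals_A22(self):
        ped = ped_from_tuples([("a", None, None), ("b", None, None),
                               ("c", "a", "b"), ("d", "a", "b")])
        A = relmat.build_A(ped)
        gi = np.array([2, 3])
        A22 = A[np.ix_(gi, gi)]
        cfg = relmat.HInverseConfig(alpha=1.0, beta=0.0)
        Hinv = relmat.build_Hinv(A, gi, A22, cfg)
        assert np.allclose(Hinv, np.linalg.inv(A), atol=1e-10)

    def test_term_by_term_oracle(self):
        """H⁻¹ equals an independent dense assembly of each term."""
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, 5)
        A = relmat.build_A(ped)
        gi = np.array([2, 3, 4])
        mm = toy_matrix([ped.ids[i] for i in gi], rng.binomial(2, 0.4, (3, 20)))
        G = relmat.build_G(mm)
        cfg = relmat.HInverseConfig()  # tau=omega=1, alpha=.9, beta=.1
        Hinv = relmat.build_Hinv(A, gi, G, cfg)
        A22 = A[np.ix_(gi, gi)]
        expect = np.linalg.inv(A)
        corr = (cfg.tau * np.linalg.inv(cfg.alpha * G + cfg.beta * A22)
                - cfg.omega * np.linalg.inv(A22))
        expect[np.ix_(gi, gi)] += corr
        assert np.allclose(Hinv, expect, atol=1e-10)
        assert np.allclose(Hinv, Hinv.T, atol=1e-12)

    def test_correction_zero_outside_genotyped_block(self):
        rng = np.random.default_rng(8)
        ped = random_pedigree(rng, 6)
        A = relmat.build_A(ped)
        gi = np.array([4, 5])
        mm = toy_matrix([ped.ids[i] for i in gi], rng.binomial(2, 0.4, (2, 15)))
        G = relmat.build_G(mm)
        Hinv = relmat.build_Hinv(A, gi, G)
        diff = Hinv - np.linalg.inv(A)
        mask = np.ones_like(diff, dtype=bool)
        mask[np.ix_(gi, gi)] = False
        assert np.allclose(diff[mask], 0, atol=1e-10)

    def test_singular_blend_raises_with_eigenvalue(self):
        A = np.eye(2)
        G = np.zeros((2, 2))
        cfg = relmat.HInverseConfig(alpha=1.0, beta=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            relmat.build_Hinv(A, np.array([0, 1]), G, cfg)


class TestPrunePedigree:
    def _chain(self, k):
        # a0 -> a1 -> ... founder chain of sires with unknown dams
        recs = [("a0", None, None)]
        for i in range(1, k):
            recs.append((f"a{i}", f"a{i-1}", None))
        # make both-or-none parents: use dummy dams
        ids = [r[0] for r in recs]
        sire = np.array([-1] + list(range(k - 1)))
        dam = np.full(k, -1)
        return sd.Pedigree(ids, sire, dam)

    def test_zero_generations_keeps_anchors_only(self):
        ped = self._chain(5)
        out = relmat.prune_pedigree(ped, ["a4"], max_generations=0)
        assert out.ids == ["a4"]
        assert out.sire[0] == -1

    def test_depth_cut(self):
        ped = self._chain(7)
        out = relmat.prune_pedigree(ped, ["a6"], max_generations=4)
        assert out.ids == ["a2", "a3", "a4", "a5", "a6"]
        # the deepest kept ancestor loses its (dropped) parent
        assert out.sire[0] == -1

    def test_all_anchors_is_identity(self, small_population):
        ped = small_population["pedigree"]
        out = relmat.prune_pedigree(ped, list(ped.ids), max_generations=4)
        assert out.ids == ped.ids
        assert np.array_equal(out.sire, ped.sire)
        assert np.array_equal(out.dam, ped.dam)


def test_blend_positive_definite_on_simulated_data(small_population):
    from hapssgwas.haploblock import BlockingConfig, build_blocks_genome
    from hapssgwas import pseudosnp as ps
    geno = small_population["genotypes"].subset_individuals(
        small_population["genotyped_ids"])
    blocks, ncsnp = build_blocks_genome(geno, BlockingConfig(0.5))
    mm = ps.assemble_matrix(geno, blocks, ncsnp, include_ncsnp=True)
    ped = small_population["pedigree"]
    rel = relmat.build_relationships(ped, mm, mm.ids)
    w = np.linalg.eigvalsh(rel.G_blend)
    assert w.min() > 0
    assert np.allclose(rel.Hinv, rel.Hinv.T, atol=1e-12)
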