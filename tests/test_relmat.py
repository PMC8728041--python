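"""Pedigree A/D, genomic G_A/G_D, scaling, blending and the H-matrix."""

import numpy as np
import pytest

from treeblup import (amatrix, blend_grm, dispersion_stats, dmatrix_pedigree,
                      grm_dominance, grm_vanraden, hmatrix, scale_grm)
from treeblup.io import GenotypeMatrix, Pedigree, RelationshipMatrix
from conftest import gene_drop_relationship, random_pedigree


class TestAmatrix:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(["a", "b", "c"], ["0"] * 3, ["0"] * 3)
        np.testing.assert_allclose(amatrix(ped).values, np.eye(3))

    def test_textbook_values(self, fullsib_pedigree):
        a = amatrix(fullsib_pedigree)
        assert a.loc("s", "x") == pytest.approx(0.5)   # parent-offspring
        assert a.loc("x", "y") == pytest.approx(0.5)   # full sibs
        assert a.loc("z", "z") == pytest.approx(1.25)  # offspring of full sibs

    def test_fullsib_offspring_matches_gene_dropping(self, fullsib_pedigree):
        a = amatrix(fullsib_pedigree)
        mc = gene_drop_relationship(fullsib_pedigree, n_drops=100_000, seed=1)
        np.testing.assert_allclose(a.values, mc, atol=0.02)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_random_pedigree_matches_gene_dropping(self, seed):
        ped = random_pedigree(n=30, n_founders=8, seed=seed)
        a = amatrix(ped)
        mc = gene_drop_relationship(ped, n_drops=40_000, seed=seed + 10)
        np.testing.assert_allclose(a.values, mc, atol=0.02)

    def test_symmetry(self):
        ped = random_pedigree(40, 10, seed=4)
        v = amatrix(ped).values
        assert np.abs(v - v.T).max() < 1e-8


class TestDmatrixPedigree:
    def test_forced_values(self, fullsib_pedigree):
        d = dmatrix_pedigree(fullsib_pedigree)
        assert d.loc("s", "d") == pytest.approx(0.0)   # unrelated
        assert d.loc("x", "y") == pytest.approx(0.25)  # full sibs
        assert d.loc("x", "x") == pytest.approx(1.0)

    def test_half_sibs_zero(self):
        ped = Pedigree(["s", "d1", "d2", "x", "y"],
                       ["0", "0", "0", "s", "s"],
                       ["0", "0", "0", "d1", "d2"])
        assert dmatrix_pedigree(ped).loc("x", "y") == pytest.approx(0.0)


class TestGrmVanraden:
    def test_single_marker_hand_example(self):
        g = GenotypeMatrix(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(grm_vanraden(g).values,
                                   [[2.0, -2.0], [-2.0, 2.0]])

    def test_centering_identity(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, 300),
                             size=(80, 300)).astype(float)
        g = GenotypeMatrix([f"i{k}" for k in range(80)],
                           [f"m{k}" for k in range(300)], calls)
        ga = grm_vanraden(g)
        assert abs(ga.values.mean()) < 1e-10

    def test_mean_diagonal_near_one_hwe(self):
        rng = np.random.default_rng(7)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, 1500),
                             size=(500, 1500)).astype(float)
        g = GenotypeMatrix([f"i{k}" for k in range(500)],
                           [f"m{k}" for k in range(1500)], calls)
        assert np.diag(grm_vanraden(g).values).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_panel_rejected(self):
        g = GenotypeMatrix(["a", "b"], ["m"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="monomorphic"):
            grm_vanraden(g)

    def test_incomplete_matrix_rejected(self):
        g = GenotypeMatrix(["a", "b"], ["m"], np.array([[np.nan], [1.0]]))
        with pytest.raises(ValueError, match="complete"):
            grm_vanraden(g)


class TestGrmDominance:
    def test_single_marker_hand_example(self):
        g = GenotypeMatrix(["a", "b", "c"], ["m"], np.array([[0.0], [1.0], [2.0]]))
        wd = np.array([-0.5, 0.5, -0.5])
        expect = np.outer(wd, wd) / 0.25
        np.testing.assert_allclose(grm_dominance(g).values, expect)

    def test_mean_diagonal_near_one_hwe(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, rng.uniform(0.15, 0.5, 1500),
                             size=(500, 1500)).astype(float)
        g = GenotypeMatrix([f"i{k}" for k in range(500)],
                           [f"m{k}" for k in range(1500)], calls)
        assert np.diag(grm_dominance(g).values).mean() == pytest.approx(1.0, abs=0.05)

    def test_fullsib_family_mean_quarter(self, pop_additive):
        truth = pop_additive["truth"]
        gd = grm_dominance(pop_additive["geno_imputed"])
        pos = {v: k for k, v in enumerate(gd.ids)}
        vals = []
        fams = {}
        for i, fam in truth.family_of.items():
            fams.setdefault(fam, []).append(i)
        for members in fams.values():
            idx = [pos[i] for i in members]
            sub = gd.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            vals.extend(sub[iu])
        assert np.mean(vals) == pytest.approx(0.25, abs=0.05)


@pytest.mark.parametrize("builder", [grm_vanraden, grm_dominance])
def test_grm_allele_swap_invariance(builder):
    """Swapping the counted allele (x -> 2-x) leaves the GRM unchanged."""
    rng = np.random.default_rng(9)
    calls = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(40, 200)).astype(float)
    ids = [f"i{k}" for k in range(40)]
    markers = [f"m{k}" for k in range(200)]
    g1 = GenotypeMatrix(ids, markers, calls)
    g2 = GenotypeMatrix(ids, markers, 2.0 - calls)
    np.testing.assert_allclose(builder(g1).values, builder(g2).values, atol=1e-10)


class TestScaleBlend:
    def test_identity_scaling(self):
        a22 = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        sc, ga = scale_grm(a22, a22)
        assert sc.beta == pytest.approx(1.0)
        assert sc.alpha == pytest.approx(0.0)

    def test_hand_solved_two_by_two(self):
        g = RelationshipMatrix(["a", "b"], np.array([[2.0, 0.0], [0.0, 2.0]]))
        a22 = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        sc, _ = scale_grm(g, a22)
        assert sc.beta == pytest.approx(0.25)
        assert sc.alpha == pytest.approx(0.5)

    def test_defining_moment_property(self, pop_additive):
        ga_raw = pop_additive["grm"]
        from treeblup import amatrix as _am
        a22 = _am(pop_additive["truth"].documented_pedigree).submatrix(ga_raw.ids)
        _, ga = scale_grm(ga_raw, a22)
        s_ga, s_a = dispersion_stats(ga), dispersion_stats(a22)
        assert s_ga["AvgDiag"] == pytest.approx(s_a["AvgDiag"], abs=1e-10)
        assert s_ga["AvgOffDiag"] == pytest.approx(s_a["AvgOffDiag"], abs=1e-10)

    def test_singular_system_rejected(self):
        g = RelationshipMatrix(["a", "b"], np.full((2, 2), 1.0))
        a22 = RelationshipMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="singular"):
            scale_grm(g, a22)

    def test_blend_endpoints(self):
        ga = RelationshipMatrix(["a", "b"], np.array([[1.2, 0.1], [0.1, 1.1]]))
        a22 = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        np.testing.assert_allclose(blend_grm(ga, a22, w=1.0).values, ga.values)
        np.testing.assert_allclose(blend_grm(ga, a22, w=0.0).values, a22.values)

    def test_blend_eigenvalue_bound(self):
        rng = np.random.default_rng(10)
        m = rng.standard_normal((6, 6))
        ga = RelationshipMatrix(list("abcdef"), m @ m.T / 6)  # PSD
        a22 = RelationshipMatrix(list("abcdef"), np.eye(6))
        gw = blend_grm(ga, a22, w=0.95)
        lam_min = np.linalg.eigvalsh(gw.values).min()
        assert lam_min >= 0.05 * 1.0 - 1e-10

    def test_blend_weight_validated(self):
        m = RelationshipMatrix(["a"], np.eye(1))
        with pytest.raises(ValueError):
            blend_grm(m, m, w=1.5)


class TestHmatrix:
    def _setup(self):
        ped = Pedigree(["s", "d", "x", "y"], ["0", "0", "s", "s"],
                       ["0", "0", "d", "d"])
        a = amatrix(ped)
        return ped, a

    def test_all_genotyped_equals_gw(self, pop_additive):
        ga = pop_additive["grm"]
        gw = RelationshipMatrix(ga.ids, ga.values, kind="Gw")
        h = hmatrix(ga, gw, ga.ids)
        np.testing.assert_array_equal(h.reorder(ga.ids).values, gw.values)

    def test_none_genotyped_equals_a(self):
        _, a = self._setup()
        gw = RelationshipMatrix([], np.zeros((0, 0)), kind="Gw")
        h = hmatrix(a, gw, [])
        np.testing.assert_array_equal(h.values, a.values)

    def test_gw_equal_a22_recovers_a(self):
        _, a = self._setup()
        a22 = a.submatrix(["x", "y"])
        gw = RelationshipMatrix(a22.ids, a22.values, kind="Gw")
        h = hmatrix(a, gw, ["x", "y"])
        np.testing.assert_allclose(h.reorder(a.ids).values, a.values, atol=1e-12)

    def test_block_formula_brute_force(self):
        """Entry-by-entry agreement with a direct evaluation of the blocks."""
        _, a = self._setup()
        geno = ["x", "y"]
        gw_vals = np.array([[1.1, 0.45], [0.45, 0.95]])
        gw = RelationshipMatrix(geno, gw_vals, kind="Gw")
        h = hmatrix(a, gw, geno)
        order = [i for i in a.ids if i not in geno] + geno
        av = a.reorder(order).values
        a11, a12, a22 = av[:2, :2], av[:2, 2:], av[2:, 2:]
        a22i = np.linalg.inv(a22)
        h11 = a11 + a12 @ a22i @ (gw_vals - a22) @ a22i @ a12.T
        h12 = a12 @ a22i @ gw_vals
        expect = np.block([[h11, h12], [h12.T, gw_vals]])
        np.testing.assert_allclose(h.reorder(order).values, expect, atol=1e-12)

    def test_id_order_nongenotyped_first(self):
        _, a = self._setup()
        gw = RelationshipMatrix(["x", "y"], np.eye(2), kind="Gw")
        h = hmatrix(a, gw, ["x", "y"])
        assert h.ids == ["s", "d", "x", "y"]


class TestDispersionStats:
    def test_identity(self):
        s = dispersion_stats(RelationshipMatrix(list("abc"), np.eye(3)))
        assert s["AvgDiag"] == 1.0
        assert s["AvgOffDiag"] == 0.0
        assert s["stdDiag"] == 0.0

    def test_constant_matrix(self):
        s = dispersion_stats(RelationshipMatrix(list("ab"), np.full((2, 2), 3.0)))
        assert s["Avg"] == 3.0
        assert s["stdDiag"] == 0.0 and s["stdOffDiag"] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        m = rng.standard_normal((5, 5))
        m = m + m.T
        rel = RelationshipMatrix(list("abcde"), m)
        perm = rel.reorder(list("ecbda"))
        s1, s2 = dispersion_stats(rel), dispersion_stats(perm)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-12)
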