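"""REML variance components, BLUP, heritability ratios, accuracy, prediction."""

import numpy as np
import pandas as pd
import pytest

from treeblup import (BLUPModel, ModelSpec, amatrix, heritability,
                      hmatrix, reml_fit, theoretical_accuracy)
from treeblup.io import Pedigree, RelationshipMatrix
from treeblup.mixedmodel import ModelFit


def _sim_grm(n, m, seed):
    """HWE genotypes -> VanRaden GRM, for quick kernel construction."""
    from treeblup import grm_vanraden
    from treeblup.io import GenotypeMatrix
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    g = GenotypeMatrix([f"i{k}" for k in range(n)],
                       [f"m{k}" for k in range(m)], calls)
    return grm_vanraden(g)


class TestRemlHalfSib:
    def test_matches_anova_sire_variance(self):
        """Balanced half-sib design: REML sigma2_a vs 4x the ANOVA sire component."""
        n_sires, n_prog = 100, 20
        h2, s2p = 0.3, 1.0
        s2a = h2 * s2p
        rng = np.random.default_rng(42)
        sire_eff = rng.normal(0.0, np.sqrt(s2a / 4), n_sires)
        y = np.repeat(sire_eff, n_prog) + rng.normal(
            0.0, np.sqrt(s2p - s2a / 4), n_sires * n_prog)
        sires = [f"S{s}" for s in range(n_sires)]
        prog = [f"P{s}_{j}" for s in range(n_sires) for j in range(n_prog)]
        ped = Pedigree(sires + prog,
                       ["0"] * n_sires + [f"S{s}" for s in range(n_sires)
                                          for _ in range(n_prog)],
                       ["0"] * (n_sires + n_sires * n_prog))
        a = amatrix(ped)
        fit = BLUPModel(random_terms=[("additive", a)]).fit(prog, y)

        # ANOVA method-of-moments oracle
        ym = y.reshape(n_sires, n_prog)
        ms_between = n_prog * ym.mean(axis=1).var(ddof=1)
        ms_within = ym.var(axis=1, ddof=1).mean()
        sigma_sire = (ms_between - ms_within) / n_prog
        mom_s2a = 4.0 * sigma_sire
        # SE of the sire component from the mean-square chi-square df
        se_sire = np.sqrt(2 / n_prog ** 2 * (
            ms_between ** 2 / (n_sires - 1 + 2)
            + ms_within ** 2 / (n_sires * (n_prog - 1) + 2)))
        assert fit.varcomp_["additive"] == pytest.approx(mom_s2a, abs=2 * 4 * se_sire)
        assert fit.converged_


class TestRemlNullBoundary:
    def test_pure_noise_drives_additive_to_floor(self):
        """h2 < 0.05 on >= 90% of seeds when y carries no genetic signal."""
        n = 1000
        grm = _sim_grm(n, 400, seed=0)
        hits = 0
        n_seeds = 20
        import warnings
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            y = rng.standard_normal(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = BLUPModel(random_terms=[("additive", grm)]).fit(grm.ids, y)
            if fit.h2_ < 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestRemlInvariances:
    def test_permutation_invariance(self, pop_additive):
        traits = pop_additive["traits"]
        grm = pop_additive["grm"]
        spec = ModelSpec("trait", [("additive", grm)])
        f1 = reml_fit(spec, traits)
        rng = np.random.default_rng(1)
        perm = traits.iloc[rng.permutation(len(traits))].reset_index(drop=True)
        f2 = reml_fit(spec, perm)
        assert f1.logl == pytest.approx(f2.logl, abs=1e-8)
        for k in f1.varcomp:
            assert f1.varcomp[k] == pytest.approx(f2.varcomp[k], abs=1e-8)

    def test_local_optimality(self, pop_additive):
        """REML optimum beats 50 random admissible variance vectors."""
        traits = pop_additive["traits"].iloc[:200]
        grm = pop_additive["grm"]
        model = BLUPModel(random_terms=[("additive", grm)])
        ids = traits["id"].to_numpy()
        y = traits["trait"].to_numpy(dtype=float)
        model.fit(ids, y)
        idsv, yv, x = model._design(ids, y)
        kerns = [grm.reorder(idsv).values]
        rng = np.random.default_rng(2)
        vy = yv.var()
        for _ in range(50):
            theta = rng.uniform(0.01, 1.5, size=2) * vy
            pieces = model._reml_pieces(theta, kerns, x, yv)
            assert pieces is None or pieces[3] <= model.logl_ + 1e-6

    def test_aic_prefers_additive_when_no_dominance(self):
        """Data simulated without dominance: AIC picks A over A+D mostly."""
        import warnings
        n = 400
        grm = _sim_grm(n, 500, seed=3)
        from treeblup import grm_dominance
        from treeblup.io import GenotypeMatrix
        rng0 = np.random.default_rng(3)
        calls = rng0.binomial(2, rng0.uniform(0.1, 0.5, 500), size=(n, 500)).astype(float)
        g = GenotypeMatrix(grm.ids, [f"m{k}" for k in range(500)], calls)
        from treeblup import grm_vanraden
        ga, gd = grm_vanraden(g), grm_dominance(g)
        la = np.linalg.cholesky(ga.values + 1e-6 * np.eye(n))
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            u = la @ rng.standard_normal(n) * np.sqrt(0.3)
            y = u + rng.standard_normal(n) * np.sqrt(0.7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fa = BLUPModel(random_terms=[("additive", ga)]).fit(ga.ids, y)
                fad = BLUPModel(random_terms=[("additive", ga),
                                              ("dominance", gd)]).fit(ga.ids, y)
            if fa.aic_ <= fad.aic_:
                wins += 1
        assert wins >= 0.8 * n_seeds


class TestHeritability:
    def test_additive_only_ratio(self):
        fit = ModelFit(varcomp={"additive": 0.57, "residual": 0.95},
                       varcomp_se={}, blup={}, pev=pd.Series(dtype=float),
                       logl=0.0, aic=0.0, h2=0.0, d2=0.0, h2_se=0.0, d2_se=0.0,
                       converged=True, n_iter=1)
        h2, d2 = heritability(fit)
        assert h2 == pytest.approx(0.57 / 1.52)
        assert abs(h2 - 0.38) <= 0.005 + 1e-12  # agrees at 2-decimal printing
        assert d2 == 0.0

    def test_dominance_ratio(self):
        fit = ModelFit(varcomp={"additive": 0.11, "dominance": 0.12,
                                "residual": 0.50},
                       varcomp_se={}, blup={}, pev=pd.Series(dtype=float),
                       logl=0.0, aic=0.0, h2=0.0, d2=0.0, h2_se=0.0, d2_se=0.0,
                       converged=True, n_iter=1)
        h2, d2 = heritability(fit)
        assert round(d2, 2) == 0.16
        assert h2 == pytest.approx(0.11 / 0.73)

    def test_zero_additive(self):
        fit = ModelFit(varcomp={"additive": 0.0, "residual": 1.0},
                       varcomp_se={}, blup={}, pev=pd.Series(dtype=float),
                       logl=0.0, aic=0.0, h2=0.0, d2=0.0, h2_se=0.0, d2_se=0.0,
                       converged=True, n_iter=1)
        assert heritability(fit) == (0.0, 0.0)


class TestTheoreticalAccuracy:
    def test_closed_forms(self):
        assert theoretical_accuracy([0.0], 1.0, [0.0])[0] == pytest.approx(1.0)
        assert theoretical_accuracy([1.0], 1.0, [0.0])[0] == pytest.approx(0.0)
        assert theoretical_accuracy([0.5], 1.0, [0.0])[0] == pytest.approx(
            np.sqrt(0.5))
        # inbreeding raises the denominator
        assert theoretical_accuracy([0.5], 1.0, [0.25])[0] == pytest.approx(
            np.sqrt(1 - 0.5 / 1.25))

    def test_negative_radicand_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            r = theoretical_accuracy([2.0], 1.0, [0.0])
        assert r[0] == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            theoretical_accuracy([0.1], 0.0)


class TestPrediction:
    def _toy(self):
        """5 individuals: 4 phenotyped, one a clone of i0, one unrelated."""
        n = 4
        rng = np.random.default_rng(7)
        base = np.array([[1.0, 0.5, 0.25, 0.0],
                         [0.5, 1.0, 0.25, 0.0],
                         [0.25, 0.25, 1.0, 0.0],
                         [0.0, 0.0, 0.0, 1.0]])
        ids = [f"i{k}" for k in range(n)]
        # append clone of i0 and an unrelated individual
        k = np.zeros((6, 6))
        k[:4, :4] = base
        k[4, :4] = base[0]
        k[:4, 4] = base[0]
        k[4, 4] = 1.0
        k[5, 5] = 1.0
        allids = ids + ["clone0", "lone"]
        y = rng.standard_normal(n)
        return RelationshipMatrix(allids, k), ids, y

    def test_unrelated_individual_predicted_zero(self):
        k, ids, y = self._toy()
        fit = BLUPModel(random_terms=[("additive", k)]).fit(ids, y)
        assert fit.predict(["lone"])[0] == pytest.approx(0.0, abs=1e-10)

    def test_clone_approaches_training_blup_as_noise_vanishes(self):
        """MME oracle: with K-entry = diagonal, the clone shares the BLUP."""
        k, ids, y = self._toy()
        # near-zero residual forced by tiny noise on an exact kernel draw
        lam = np.linalg.cholesky(k.values[:4, :4] + 1e-10 * np.eye(4))
        u = lam @ np.random.default_rng(8).standard_normal(4)
        fit = BLUPModel(random_terms=[("additive", k)]).fit(ids, u)
        pred = fit.predict(["clone0", "i0"])
        assert pred[0] == pytest.approx(pred[1], abs=1e-6)
        # direct mixed-model-equation oracle for the training BLUP
        s2a, s2e = fit.varcomp_["additive"], fit.varcomp_["residual"]
        kinv = np.linalg.inv(k.values[:4, :4])
        z = np.eye(4)
        x = np.ones((4, 1))
        lhs = np.block([[x.T @ x, x.T @ z],
                        [z.T @ x, z.T @ z + kinv * s2e / s2a]])
        rhs = np.concatenate([x.T @ u, z.T @ u])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(fit.blup_["additive"].loc[ids], sol[1:],
                                   atol=1e-8)

    def test_predictions_linear_in_y(self):
        k, ids, y = self._toy()
        f1 = BLUPModel(random_terms=[("additive", k)]).fit(ids, y)
        # linearity at fixed variance ratios: refit with frozen components
        m2 = BLUPModel(random_terms=[("additive", k)], max_iter=0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m2.fit(ids, y)
            m3 = BLUPModel(random_terms=[("additive", k)], max_iter=0).fit(ids, 2 * y)
        np.testing.assert_allclose(2 * m2.blup_["additive"].to_numpy(),
                                   m3.blup_["additive"].to_numpy(), atol=1e-10)

    def test_missing_id_rejected(self):
        k, ids, y = self._toy()
        fit = BLUPModel(random_terms=[("additive", k)]).fit(ids, y)
        with pytest.raises(ValueError, match="absent"):
            fit.predict(["ghost"])


class TestSingleStepIdentity:
    def test_ssgblup_equals_gblup_when_all_genotyped(self, pop_additive):
        traits = pop_additive["traits"].iloc[:250]
        ga = pop_additive["grm"]
        gw = RelationshipMatrix(ga.ids, ga.values, kind="Gw")
        h = hmatrix(ga, gw, ga.ids)
        fg = reml_fit(ModelSpec("trait", [("additive", ga)]), traits)
        fh = reml_fit(ModelSpec("trait", [("additive", h)]), traits)
        for k in fg.varcomp:
            assert fg.varcomp[k] == pytest.approx(fh.varcomp[k], abs=1e-6)
        np.testing.assert_allclose(
            fg.blup["additive"].to_numpy(),
            fh.blup["additive"].reindex(fg.blup["additive"].index).to_numpy(),
            atol=1e-6)
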