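"""REML variance components and BLUP for the individual-tree mixed model.

The model is  ``y = X mu + sum_k Z_k u_k + e``  with one record per
phenotyped individual, ``u_k ~ N(0, K_k sigma2_k)`` for arbitrary
relationship matrices K_k (pedigree A, genomic G, dominance D/G_D,
single-step H, imported IBD), and ``e ~ N(0, I sigma2_e)``.

Variance components maximize the restricted likelihood by Newton-Raphson
with direct inversion of the phenotype covariance and the
average-information approximation to the Hessian, stabilized by
step-halving and projection of components onto the admissible region.
BLUPs are recovered for *all* individuals present in the relationship
matrices (not only the phenotyped ones), which is what cross-validation
and single-step evaluation of nongenotyped trees rely on.

The estimator follows the scikit-learn protocol: construct with the
model structure, ``fit(ids, y)``, read fitted attributes with trailing
underscores, ``predict(ids)`` for breeding or genotypic values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import RelationshipMatrix

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-8


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Declarative model description (thin layer over the estimator)
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    response: str
    random_terms: list[tuple[str, RelationshipMatrix]]
    covariates: pd.DataFrame | None = None   # indexed by id, fixed covariates
    label: str = ""


@dataclass
class ModelFit:
    """Result container for one REML fit."""

    varcomp: dict[str, float]
    varcomp_se: dict[str, float]
    blup: dict[str, pd.Series]
    pev: pd.Series
    logl: float
    aic: float
    h2: float
    d2: float
    h2_se: float
    d2_se: float
    converged: bool
    n_iter: int
    label: str = ""
    model: "BLUPModel | None" = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class BLUPModel(BaseEstimator):
    """REML + BLUP estimator for one trait with arbitrary covariance kernels.

    Parameters
    ----------
    random_terms : list of (name, RelationshipMatrix)
        Covariance structures of the random effects; the first term named
        ``"additive"`` (or simply the first term) provides PEV and
        breeding values, an optional term named ``"dominance"`` the
        dominance deviations.
    covariates : DataFrame indexed by id, optional
        Fixed-effect covariates beyond the intercept (e.g. the
        inbreeding coefficient).
    max_iter, tol_logl, tol_param : numerics of the Newton iteration.

    Attributes (after :meth:`fit`)
    ------------------------------
    varcomp_, varcomp_se_ : dict name -> estimate / standard error
        (the residual is keyed ``"residual"``).
    blup_ : dict name -> Series over *all* ids of that term's K.
    pev_ : Series, prediction error variance of the additive effect.
    logl_, aic_, h2_, d2_, h2_se_, d2_se_, converged_, n_iter_.
    """

    def __init__(self, random_terms=None, covariates=None, max_iter=100,
                 tol_logl=1e-8, tol_param=1e-6, verbose=False):
        self.random_terms = random_terms
        self.covariates = covariates
        self.max_iter = max_iter
        self.tol_logl = tol_logl
        self.tol_param = tol_param
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _design(self, ids, y):
        ids = [str(i) for i in np.asarray(ids).ravel()]
        y = np.asarray(y, dtype=float).ravel()
        if len(ids) != len(y):
            raise ValueError("ids and y have different lengths")
        keep = ~np.isnan(y)
        ids = [i for i, k in zip(ids, keep) if k]
        y = y[keep]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate phenotype records per individual")
        for name, k in self.random_terms:
            missing = set(ids) - set(k.ids)
            if missing:
                raise ValueError(
                    f"term {name!r}: {len(missing)} phenotyped ids absent from K "
                    f"(e.g. {sorted(missing)[:3]})")
        x = np.ones((len(ids), 1))
        if self.covariates is not None:
            cov = self.covariates.loc[[str(i) for i in ids]].to_numpy(dtype=float)
            x = np.hstack([x, cov])
        return ids, y, x

    @staticmethod
    def _reml_pieces(theta, kerns, x, y):
        n = len(y)
        v = theta[-1] * np.eye(n)
        for t, k in zip(theta[:-1], kerns):
            v += t * k
        vinv = np.linalg.inv(v)
        xtvx = x.T @ vinv @ x
        sign, logdet_v = np.linalg.slogdet(v)
        if sign <= 0:
            return None
        sign2, logdet_x = np.linalg.slogdet(xtvx)
        if sign2 <= 0:
            return None
        vinv_x = vinv @ x
        proj = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
        py = proj @ y
        logl = -0.5 * (logdet_v + logdet_x + float(y @ py))
        return vinv, proj, py, logl

    def fit(self, X, y):
        """Estimate variance components and BLUPs.

        ``X`` is a sequence of individual ids aligned with the phenotype
        vector ``y`` (NaN phenotypes are dropped).
        """
        if not self.random_terms:
            raise ValueError("at least one random term is required")
        ids, yv, xmat = self._design(X, y)
        n = len(yv)
        if n < 3:
            raise ValueError("too few phenotyped individuals")
        kerns = [k.reorder(ids).values for _, k in self.random_terms]
        names = [name for name, _ in self.random_terms]
        n_terms = len(kerns)

        theta = np.full(n_terms + 1, 0.5 * yv.var() / (n_terms + 1))
        theta = np.maximum(theta, VAR_FLOOR)
        pieces = self._reml_pieces(theta, kerns, xmat, yv)
        if pieces is None:
            raise ValueError("initial covariance is singular")
        _, proj, py, logl = pieces

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # score and average information
            tvec = [k @ py for k in kerns] + [py]
            score = np.empty(n_terms + 1)
            for k_idx in range(n_terms):
                score[k_idx] = -0.5 * (np.sum(proj * kerns[k_idx])
                                       - float(py @ kerns[k_idx] @ py))
            score[-1] = -0.5 * (np.trace(proj) - float(py @ py))
            tmat = np.column_stack(tvec)
            ai = 0.5 * tmat.T @ proj @ tmat

            # freeze components stuck at the floor with inward-pointing score
            frozen = (theta <= VAR_FLOOR * 1.0001) & (score < 0)
            free = ~frozen
            delta = np.zeros_like(theta)
            ai_free = ai[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(ai_free, score[free])
            except np.linalg.LinAlgError:
                delta[free] = score[free] / max(np.abs(np.diag(ai_free)).max(), 1.0)

            step = 1.0
            improved = False
            for _ in range(25):
                cand = np.maximum(theta + step * delta, VAR_FLOOR)
                pieces = self._reml_pieces(cand, kerns, xmat, yv)
                if pieces is not None and pieces[3] >= logl - 1e-12:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                break
            new_logl = pieces[3]
            param_change = np.abs(cand - theta).max()
            logl_change = abs(new_logl - logl)
            theta, (_, proj, py, logl) = cand, pieces
            if self.verbose:
                log.info("iter %d: logL=%.6f theta=%s", it, logl, theta)
            if (logl_change < self.tol_logl * (1.0 + abs(logl))
                    or param_change < self.tol_param):
                converged = True
                break

        if not converged:
            warnings.warn(f"REML did not converge in {it} iterations",
                          ConvergenceWarning)

        # standard errors from the inverse average information at the optimum
        tvec = [k @ py for k in kerns] + [py]
        tmat = np.column_stack(tvec)
        ai = 0.5 * tmat.T @ proj @ tmat
        try:
            ai_inv = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            ai_inv = np.full_like(ai, np.nan)
        se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))

        self.ids_ = ids
        self.theta_ = theta
        self.varcomp_ = {**{nm: float(t) for nm, t in zip(names, theta[:-1])},
                         "residual": float(theta[-1])}
        self.varcomp_se_ = {**{nm: float(s) for nm, s in zip(names, se[:-1])},
                            "residual": float(se[-1])}
        self.ai_cov_ = ai_inv
        self.logl_ = float(logl)
        self.aic_ = -2.0 * float(logl) + 2.0 * (n_terms + 1)
        self.converged_ = converged
        self.n_iter_ = it

        # BLUPs over all ids of each term's K: u_k = sigma2_k K Z' P y
        self.blup_ = {}
        for (name, kmat), t in zip(self.random_terms, theta[:-1]):
            pos = {v: j for j, v in enumerate(kmat.ids)}
            kz = kmat.values[:, [pos[i] for i in ids]]
            self.blup_[name] = pd.Series(t * (kz @ py), index=kmat.ids, name=name)

        # PEV of the additive effect from the MME-inverse identity
        #   Var(u - u_hat) = s2 K - s2^2 K Z' P Z K
        a_idx = names.index("additive") if "additive" in names else 0
        a_name, a_k = self.random_terms[a_idx]
        s2a = theta[a_idx]
        kfull = a_k.values
        pos = {v: j for j, v in enumerate(a_k.ids)}
        m = kfull[:, [pos[i] for i in ids]]      # q x n
        pm = proj @ m.T                          # n x q
        pev = s2a * np.diag(kfull) - s2a ** 2 * np.einsum("qn,nq->q", m, pm)
        self.pev_ = pd.Series(np.maximum(pev, 0.0), index=a_k.ids, name="pev")

        # heritability ratios with delta-method SEs
        total = float(theta.sum())
        grads = np.full((2, n_terms + 1), np.nan)
        h2 = float(theta[a_idx]) / total
        grads[0] = -theta[a_idx] / total ** 2
        grads[0, a_idx] += 1.0 / total
        d_idx = names.index("dominance") if "dominance" in names else None
        if d_idx is not None:
            d2 = float(theta[d_idx]) / total
            grads[1] = -theta[d_idx] / total ** 2
            grads[1, d_idx] += 1.0 / total
        else:
            d2 = 0.0
            grads[1] = 0.0
        with np.errstate(invalid="ignore"):
            h2_se = float(np.sqrt(max(grads[0] @ ai_inv @ grads[0], 0.0)))
            d2_se = float(np.sqrt(max(grads[1] @ ai_inv @ grads[1], 0.0)))
        self.h2_, self.d2_ = h2, d2
        self.h2_se_, self.d2_se_ = h2_se, d2_se
        return self

    def predict(self, X, kind: str = "additive") -> np.ndarray:
        """Predicted effects for the requested ids.

        ``kind="additive"`` returns breeding values; ``kind="genotypic"``
        adds the dominance deviation when a dominance term was fitted.
        """
        ids = [str(i) for i in np.asarray(X).ravel()]
        a_name = "additive" if "additive" in self.blup_ else next(iter(self.blup_))
        out = self.blup_[a_name].reindex(ids)
        if out.isna().any():
            missing = sorted(set(ids) - set(self.blup_[a_name].index))
            raise ValueError(f"ids absent from the fitted relationship matrix: "
                             f"{missing[:3]}")
        if kind == "genotypic" and "dominance" in self.blup_:
            out = out + self.blup_["dominance"].reindex(ids)
        elif kind not in ("additive", "genotypic"):
            raise ValueError(f"unknown prediction kind {kind!r}")
        return out.to_numpy()

    def to_fit(self, label: str = "") -> ModelFit:
        return ModelFit(
            varcomp=self.varcomp_, varcomp_se=self.varcomp_se_, blup=self.blup_,
            pev=self.pev_, logl=self.logl_, aic=self.aic_, h2=self.h2_,
            d2=self.d2_, h2_se=self.h2_se_, d2_se=self.d2_se_,
            converged=self.converged_, n_iter=self.n_iter_, label=label,
            model=self)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def reml_fit(spec: ModelSpec, traits: pd.DataFrame) -> ModelFit:
    """Fit *spec* to the trait table (columns ``id`` and ``spec.response``)."""
    model = BLUPModel(random_terms=spec.random_terms, covariates=spec.covariates)
    model.fit(traits["id"].to_numpy(), traits[spec.response].to_numpy(dtype=float))
    return model.to_fit(label=spec.label)


def heritability(fit: ModelFit) -> tuple[float, float]:
    """Narrow-sense h2 and dominance ratio d2 from a fit.

    ``h2 = s2_a / (s2_a + s2_d + s2_e)``; ``d2`` analogous (0 without a
    dominance term).
    """
    total = sum(fit.varcomp.values())
    if total <= 0:
        raise ValueError("zero total variance")
    h2 = fit.varcomp.get("additive", 0.0) / total
    d2 = fit.varcomp.get("dominance", 0.0) / total
    return h2, d2


def theoretical_accuracy(pev, sigma2_a: float, f=0.0) -> np.ndarray:
    """Per-individual accuracy ``r_i = sqrt(1 - PEV_i / (s2_a (1 + F_i)))``.

    The radicand is clipped to [0, 1] with a warning when negative
    (possible under numerical error or strong shrinkage).
    """
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    pev = np.asarray(pev, dtype=float)
    f = np.broadcast_to(np.asarray(f, dtype=float), pev.shape)
    rad = 1.0 - pev / (sigma2_a * (1.0 + f))
    if (rad < -1e-12).any():
        warnings.warn("negative radicand in theoretical accuracy; clipping to 0")
    return np.sqrt(np.clip(rad, 0.0, 1.0))


def predict_unphenotyped(spec: ModelSpec, traits: pd.DataFrame,
                         test_ids) -> pd.Series:
    """Fit on all records except *test_ids*, predict those via covariance.

    Test individuals must be present in every relationship matrix; their
    predictions flow through the K-covariance with the training set.
    """
    test = {str(i) for i in test_ids}
    for name, k in spec.random_terms:
        absent = test - set(k.ids)
        if absent:
            raise ValueError(f"test ids absent from term {name!r}: {sorted(absent)[:3]}")
    train = traits[~traits["id"].astype(str).isin(test)]
    fit = reml_fit(spec, train)
    preds = fit.model.predict(sorted(test))
    return pd.Series(preds, index=sorted(test))
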