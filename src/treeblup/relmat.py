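"""Pedigree and genomic relationship matrices, and the single-step H-matrix.

Implements the classical tabular numerator relationship matrix (with
inbreeding), the pedigree dominance matrix, the marker-based additive
(VanRaden) and dominance (Vitezica-type) genomic relationship matrices,
the compatibility rescaling of G onto the pedigree A22 block, the
weighted blend Gw, and the combined H-matrix used by single-step GBLUP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, Pedigree, RelationshipMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pedigree matrices
# ---------------------------------------------------------------------------

def amatrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    ``a_ii = 1 + F_i`` with ``F_i = 0.5 * a_{sire,dam}``;
    ``a_ij = 0.5 * (a_{j,sire(i)} + a_{j,dam(i)})`` for j preceding i.
    Unknown parents contribute zero (unrelated, non-inbred founders).
    """
    n = len(ped)
    # row/col 0 is a phantom "unknown parent" with zero relationships
    a = np.zeros((n + 1, n + 1))
    s = ped.sire_idx + 1
    d = ped.dam_idx + 1
    for i in range(1, n + 1):
        si, di = s[i - 1], d[i - 1]
        a[i, :i] = 0.5 * (a[si, :i] + a[di, :i])
        a[:i, i] = a[i, :i]
        a[i, i] = 1.0 + 0.5 * a[si, di]
    return RelationshipMatrix(ped.ids, a[1:, 1:], kind="A")


def inbreeding_from_pedigree(ped: Pedigree) -> dict[str, float]:
    """Pedigree inbreeding coefficients F_i = a_ii - 1."""
    a = amatrix(ped)
    return {i: float(a.values[k, k] - 1.0) for k, i in enumerate(ped.ids)}


def dmatrix_pedigree(ped: Pedigree, a: RelationshipMatrix | None = None) -> RelationshipMatrix:
    """Pedigree dominance relationship matrix (classical, ignoring inbreeding).

    Off-diagonal ``d_ij = 0.25*(a_{s(i)s(j)} a_{d(i)d(j)} + a_{s(i)d(j)} a_{d(i)s(j)})``;
    the diagonal is set to 1; unknown-parent terms are zero.
    """
    if a is None:
        a = amatrix(ped)
    av = a.reorder(ped.ids).values
    n = len(ped)
    aa = np.zeros((n + 1, n + 1))
    aa[1:, 1:] = av
    s = ped.sire_idx + 1
    d = ped.dam_idx + 1
    dd = 0.25 * (aa[np.ix_(s, s)] * aa[np.ix_(d, d)] + aa[np.ix_(s, d)] * aa[np.ix_(d, s)])
    np.fill_diagonal(dd, 1.0)
    return RelationshipMatrix(ped.ids, dd, kind="D_ped")


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------

def _check_complete(g: GenotypeMatrix):
    if not g.is_complete:
        raise ValueError("genomic relationship matrices require a complete "
                         "(imputed) genotype matrix")


def grm_vanraden(g: GenotypeMatrix, p: np.ndarray | None = None) -> RelationshipMatrix:
    """Additive genomic relationship matrix (VanRaden method 1).

    ``G_A = W_a W_a' / (2 sum_j p_j q_j)`` with ``W_a = X - 2p`` (genotype
    coding 0/1/2 minus twice the allele frequency).  Frequencies default to
    the analyzed sample's.
    """
    _check_complete(g)
    p = g.p if p is None else np.asarray(p, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    w = g.calls - 2.0 * p
    return RelationshipMatrix(g.ids, (w @ w.T) / denom, kind="G_A")


def grm_dominance(g: GenotypeMatrix, p: np.ndarray | None = None) -> RelationshipMatrix:
    """Dominance genomic relationship matrix (Vitezica parameterization).

    ``G_D = W_d W_d' / sum_j (2 p_j q_j)^2`` with per-genotype entries
    ``{-2q^2, 2pq, -2p^2}`` for counted-allele genotypes {2, 1, 0} — the
    zero-mean coding under Hardy-Weinberg proportions (its variance per
    marker is exactly (2pq)^2, matching the denominator).  Imputed
    fractional genotypes are mapped by linear interpolation between the
    three states.
    """
    _check_complete(g)
    p = g.p if p is None else np.asarray(p, dtype=float)
    q = 1.0 - p
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero dominance denominator")
    w = dominance_coding(g.calls, p)
    return RelationshipMatrix(g.ids, (w @ w.T) / denom, kind="G_D")


def dominance_coding(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Zero-mean dominance covariate: {0,1,2} -> {-2p^2, 2pq, -2q^2}.

    Piecewise linear between states for fractional (imputed) genotypes.
    """
    q = 1.0 - p
    lo = -2.0 * p ** 2 + x * (2.0 * p * q + 2.0 * p ** 2)          # x in [0, 1]
    hi = 2.0 * p * q + (x - 1.0) * (-2.0 * q ** 2 - 2.0 * p * q)   # x in [1, 2]
    return np.where(x <= 1.0, lo, hi)


# ---------------------------------------------------------------------------
# Single-step machinery
# ---------------------------------------------------------------------------

@dataclass
class GrmScaling:
    beta: float
    alpha: float


def dispersion_stats(m: RelationshipMatrix) -> dict[str, float]:
    """Avg / AvgDiag / AvgOffDiag / stdDiag / stdOffDiag of a square matrix.

    Off-diagonal statistics are over the strict upper triangle.
    """
    v = m.values
    n = v.shape[0]
    diag = np.diag(v)
    iu = np.triu_indices(n, k=1)
    off = v[iu]
    return {
        "Avg": float(v.mean()),
        "AvgDiag": float(diag.mean()),
        "AvgOffDiag": float(off.mean()) if off.size else 0.0,
        "stdDiag": float(diag.std()),
        "stdOffDiag": float(off.std()) if off.size else 0.0,
    }


def scale_grm(g: RelationshipMatrix, a22: RelationshipMatrix):
    """Rescale G to the scale of the pedigree block A22: ``Ga = beta*G + alpha``.

    beta and alpha solve the two moment conditions
    ``Avg.diag(G)*beta + alpha = Avg.diag(A22)`` and
    ``Avg.offdiag(G)*beta + alpha = Avg.offdiag(A22)``.

    Returns ``(scaling, Ga)`` with the ids ordered as in *a22*.
    """
    if set(g.ids) != set(a22.ids):
        raise ValueError("G and A22 must cover the same individuals")
    g = g.reorder(a22.ids)
    sg = dispersion_stats(g)
    sa = dispersion_stats(a22)
    dg, og = sg["AvgDiag"], sg["AvgOffDiag"]
    if abs(dg - og) < 1e-12:
        raise ValueError("Avg.diag(G) == Avg.offdiag(G): scaling system singular")
    beta = (sa["AvgDiag"] - sa["AvgOffDiag"]) / (dg - og)
    alpha = sa["AvgDiag"] - dg * beta
    ga = RelationshipMatrix(a22.ids, beta * g.values + alpha, kind="Ga")
    return GrmScaling(beta=beta, alpha=alpha), ga


def blend_grm(ga: RelationshipMatrix, a22: RelationshipMatrix,
              w: float = 0.95, min_eig: float = 1e-6) -> RelationshipMatrix:
    """Weighted blend ``Gw = w*Ga + (1-w)*A22`` with eigenvalue flooring.

    The small pedigree weight keeps Gw invertible; if the blend is still
    not positive definite its eigenvalues are floored at *min_eig* with a
    logged warning.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend weight w must be in [0, 1]")
    if set(ga.ids) != set(a22.ids):
        raise ValueError("Ga and A22 must cover the same individuals")
    ga = ga.reorder(a22.ids)
    gw = w * ga.values + (1.0 - w) * a22.values
    evals = np.linalg.eigvalsh(gw)
    if evals.min() < min_eig:
        log.warning("blended Gw not positive definite (min eig %.3g); flooring at %.1g",
                    evals.min(), min_eig)
        lam, vec = np.linalg.eigh(gw)
        gw = (vec * np.maximum(lam, min_eig)) @ vec.T
        gw = 0.5 * (gw + gw.T)
    return RelationshipMatrix(a22.ids, gw, kind="Gw")


def hmatrix(a: RelationshipMatrix, gw: RelationshipMatrix,
            genotyped_ids) -> RelationshipMatrix:
    """Combined single-step H-matrix from pedigree A and weighted genomic Gw.

    With the pedigree matrix partitioned into nongenotyped (1) and
    genotyped (2) blocks::

        H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21
        H12 = A12 A22^-1 Gw
        H22 = Gw

    The result is returned in A's id order (nongenotyped block first,
    then genotyped, stable by input order).
    """
    genotyped = [str(i) for i in genotyped_ids]
    gset = set(genotyped)
    if not gset.issubset(a.ids):
        raise ValueError("genotyped ids must be a subset of the pedigree matrix ids")
    if set(gw.ids) != gset:
        raise ValueError("Gw must cover exactly the genotyped ids")
    non = [i for i in a.ids if i not in gset]
    geno = [i for i in a.ids if i in gset]
    order = non + geno
    av = a.reorder(order).values
    n1 = len(non)
    a11 = av[:n1, :n1]
    a12 = av[:n1, n1:]
    a22 = av[n1:, n1:]
    gwv = gw.reorder(geno).values
    if n1 == 0:
        h = gwv
    elif len(geno) == 0:
        h = a11
    else:
        try:
            t = np.linalg.solve(a22, a12.T)       # A22^-1 A21
        except np.linalg.LinAlgError as e:
            raise ValueError("A22 is singular; cannot build H") from e
        h11 = a11 + t.T @ (gwv - a22) @ t
        h12 = t.T @ gwv
        h = np.block([[h11, h12], [h12.T, gwv]])
        h = 0.5 * (h + h.T)
    return RelationshipMatrix(order, h, kind="H")


def make_hmatrix(ped: Pedigree, g: RelationshipMatrix, w: float = 0.95,
                 rescale: bool = True) -> RelationshipMatrix:
    """Convenience path: A from pedigree, scale G to A22, blend, assemble H.

    *rescale=False* skips the beta/alpha compatibility step (useful for
    externally computed IBD matrices that are already on the pedigree
    scale).
    """
    a = amatrix(ped)
    a22 = a.submatrix(g.ids)
    if rescale:
        _, ga = scale_grm(g, a22)
    else:
        ga = RelationshipMatrix(a22.ids, g.reorder(a22.ids).values, kind="Ga")
    gw = blend_grm(ga, a22, w=w)
    return hmatrix(a, gw, g.ids)
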