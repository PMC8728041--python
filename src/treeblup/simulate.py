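"""Synthetic breeding populations for testing the genomic-evaluation pipeline.

The generator emulates a two-generation forest-tree breeding population:
a founder set of unrelated parents genotyped at unlinked biallelic
markers, and families produced by open pollination (OP, father unknown,
with a configurable selfing probability), controlled pollination (CP,
both parents recorded) and polymix crosses (father drawn from a declared
pollen pool but recorded as unknown).  Traits are controlled by a subset
of the markers acting as QTL with additive and (directional) dominance
effects; selfing induces inbreeding and hence inbreeding depression when
dominance is directional.

Every simulated quantity of interest (true pedigree, true breeding
values, dominance deviations, QTL effects, inbreeding coefficients) is
retained in :class:`SimulationTruth` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import UNKNOWN, GenotypeMatrix, Pedigree
from .relmat import inbreeding_from_pedigree


def _default_family_plan() -> list[tuple[str, int]]:
    # 199 families (139 OP, 27 CP, 33 polymix) of ~41 progeny: the layout of
    # a third-generation E. nitens-style progeny-trial population.
    return ([("OP", 41)] * 139 + [("CP", 41)] * 27 + [("POLYMIX", 41)] * 33)


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding population.

    Variances are on the (standardized) trait scale; the defaults give a
    moderately heritable growth-type trait (h2 = 0.2, d2 = 0.15) with
    fully directional dominance, the regime in which inbreeding
    depression is expected.
    """

    n_founders: int = 330
    n_markers: int = 3514
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 300
    sigma2_a: float = 0.20
    sigma2_d: float = 0.15
    sigma2_e: float = 0.65
    dominance_direction: float = 1.0   # fraction of QTL with positive d
    selfing_rate: float = 0.15         # OP matings only
    family_plan: list[tuple[str, int]] = field(default_factory=_default_family_plan)
    n_trials: int = 6
    trial_effect_sd: float = 0.5
    polymix_pool_size: int = 5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for name in ("sigma2_a", "sigma2_d", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dominance_direction", "selfing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.family_plan:
            raise ValueError("family_plan must be non-empty")
        for mt, k in self.family_plan:
            if mt not in ("OP", "CP", "POLYMIX"):
                raise ValueError(f"unknown mating type {mt!r}")
            if k < 1:
                raise ValueError("family sizes must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated population."""

    true_pedigree: Pedigree
    documented_pedigree: Pedigree
    tbv: pd.Series          # true breeding values (additive)
    tdd: pd.Series          # true dominance deviations
    qtl_effects: pd.DataFrame  # index marker, columns a, d
    true_F: pd.Series       # pedigree inbreeding coefficients
    pools: dict[str, list[str]] = field(default_factory=dict)  # family -> candidate sires
    errors: list[dict] = field(default_factory=list)           # injected pedigree errors
    family_of: dict[str, str] = field(default_factory=dict)
    mating_type_of: dict[str, str] = field(default_factory=dict)


def simulate_founders(cfg: SimConfig) -> GenotypeMatrix:
    """Draw founder genotypes marker-wise from Hardy-Weinberg proportions.

    Allele frequencies are uniform on ``cfg.maf_range``; genotypes are
    Binomial(2, p) per founder and marker.  Deterministic given
    ``cfg.seed``.
    """
    if cfg.n_founders < 2 or cfg.n_markers < 1:
        raise ValueError("need n_founders >= 2 and n_markers >= 1")
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    calls = rng.binomial(2, p, size=(cfg.n_founders, cfg.n_markers)).astype(float)
    width = len(str(cfg.n_founders))
    ids = [f"P{k + 1:0{width}d}" for k in range(cfg.n_founders)]
    markers = [f"M{j + 1}" for j in range(cfg.n_markers)]
    return GenotypeMatrix(ids, markers, calls)


def _gamete(rng: np.random.Generator, genotype_row: np.ndarray) -> np.ndarray:
    """One transmitted allele count per (unlinked) marker: Bernoulli(g/2)."""
    return rng.binomial(1, genotype_row / 2.0).astype(float)


def simulate_pedigree_and_genotypes(founders: GenotypeMatrix,
                                    cfg: SimConfig) -> tuple[SimulationTruth, GenotypeMatrix]:
    """Mate founders per ``cfg.family_plan`` and gene-drop progeny genotypes.

    Dams are drawn without replacement from the founders (one family per
    dam).  CP sires are distinct founders and are recorded; OP sires are
    the dam itself with probability ``selfing_rate`` (else a random other
    founder) and are recorded as unknown; POLYMIX sires are drawn from a
    declared pollen pool and recorded as unknown, with pool membership
    retained in the truth.  True inbreeding coefficients come from the
    A-matrix of the true pedigree.

    Returns the truth record and the combined founder+progeny genotype
    matrix.
    """
    if founders.n_individuals == 0:
        raise ValueError("founder set is empty")
    n_fam = len(cfg.family_plan)
    if n_fam > founders.n_individuals:
        raise ValueError(f"family_plan requests {n_fam} dams but only "
                         f"{founders.n_individuals} founders exist")
    if any(mt == "POLYMIX" for mt, _ in cfg.family_plan) and cfg.polymix_pool_size < 1:
        raise ValueError("empty pollen pool")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    fids = founders.ids
    dams = rng.choice(fids, size=n_fam, replace=False)

    rows_id, rows_true_s, rows_true_d = [], [], []
    doc_sire: dict[str, str] = {}
    family_of: dict[str, str] = {}
    mating_of: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    prog_calls = []
    fidx = {v: k for k, v in enumerate(fids)}
    counter = 0
    for f, ((mtype, n_prog), dam) in enumerate(zip(cfg.family_plan, dams)):
        fam = f"F{f + 1:03d}"
        others = [x for x in fids if x != dam]
        if mtype == "CP":
            sire_fixed = rng.choice(others)
        elif mtype == "POLYMIX":
            pool = list(rng.choice(others, size=min(cfg.polymix_pool_size, len(others)),
                                   replace=False))
            pools[fam] = pool
        for _ in range(n_prog):
            counter += 1
            child = f"T{counter:05d}"
            if mtype == "CP":
                sire = sire_fixed
                doc_sire[child] = sire
            elif mtype == "OP":
                if rng.random() < cfg.selfing_rate:
                    sire = dam
                else:
                    sire = rng.choice(others)
                doc_sire[child] = UNKNOWN
            else:  # POLYMIX
                sire = pool[rng.integers(len(pool))]
                doc_sire[child] = UNKNOWN
            rows_id.append(child)
            rows_true_s.append(sire)
            rows_true_d.append(dam)
            family_of[child] = fam
            mating_of[child] = mtype
            g_child = (_gamete(rng, founders.calls[fidx[sire]])
                       + _gamete(rng, founders.calls[fidx[dam]]))
            prog_calls.append(g_child)

    founder_rows = {i: (UNKNOWN, UNKNOWN) for i in fids}
    all_ids = fids + rows_id
    true_ped = Pedigree(
        all_ids,
        [founder_rows[i][0] for i in fids] + rows_true_s,
        [founder_rows[i][1] for i in fids] + rows_true_d,
        family=family_of, mating_type=mating_of)
    doc_ped = Pedigree(
        all_ids,
        [UNKNOWN] * len(fids) + [doc_sire[c] for c in rows_id],
        [UNKNOWN] * len(fids) + rows_true_d,
        family=family_of, mating_type=mating_of)

    f_coef = inbreeding_from_pedigree(true_ped)
    genotypes = GenotypeMatrix(
        all_ids, founders.markers,
        np.vstack([founders.calls, np.array(prog_calls)]))
    truth = SimulationTruth(
        true_pedigree=true_ped, documented_pedigree=doc_ped,
        tbv=pd.Series(0.0, index=all_ids), tdd=pd.Series(0.0, index=all_ids),
        qtl_effects=pd.DataFrame(columns=["a", "d"]),
        true_F=pd.Series({i: f_coef[i] for i in all_ids}),
        pools=pools, family_of=family_of, mating_type_of=mating_of)
    return truth, genotypes


def simulate_traits(genotypes: GenotypeMatrix, truth: SimulationTruth,
                    cfg: SimConfig) -> pd.DataFrame:
    """Simulate one trait from QTL effects; fills tbv/tdd/qtl_effects in *truth*.

    ``n_qtl`` markers are chosen as QTL.  Genotypic effects per QTL are a
    genotypic additive effect ``a_j`` (N(0,1) draw) and a dominance
    effect ``d_j`` (half-normal magnitude, a fraction
    ``dominance_direction`` positive).  These are decomposed at founder
    allele frequencies into statistical breeding values (average effect
    ``alpha_j = a_j + d_j (q_j - p_j)`` on the centered genotype) and
    dominance deviations (zero-mean dominance covariate scaled by
    ``d_j``), and rescaled so the realized additive and dominance
    variances in the founder sample equal ``sigma2_a`` and ``sigma2_d``
    exactly.  Phenotypes (progeny only) add a round-robin trial effect
    and N(0, sigma2_e) noise.

    Returns a trait table with columns ``id, trial, replicate, trait``.
    """
    from .relmat import dominance_coding

    if cfg.n_qtl > genotypes.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    if cfg.sigma2_d > 0 and cfg.n_qtl == 0:
        raise ValueError("sigma2_d > 0 requires n_qtl > 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    founder_ids = truth.true_pedigree.founders
    pos = {v: k for k, v in enumerate(genotypes.ids)}
    founder_rows = [pos[i] for i in founder_ids]

    qtl_cols = rng.choice(genotypes.n_markers, size=cfg.n_qtl, replace=False)
    x = genotypes.calls[:, qtl_cols]
    p = x[founder_rows].mean(axis=0) / 2.0  # founder allele frequencies
    wa = x - 2.0 * p

    a = rng.standard_normal(cfg.n_qtl)
    d = np.abs(rng.standard_normal(cfg.n_qtl))
    neg = rng.random(cfg.n_qtl) >= cfg.dominance_direction
    d[neg] *= -1.0

    # scale dominance deviations to hit sigma2_d in the founder sample
    wd = dominance_coding(x, p)
    dom_raw = wd @ d
    vd = dom_raw[founder_rows].var()
    if cfg.sigma2_d == 0.0 or vd == 0.0:
        d = np.zeros_like(d)
        dom_score = np.zeros_like(dom_raw)
    else:
        d *= np.sqrt(cfg.sigma2_d / vd)
        dom_score = wd @ d

    # breeding values: alpha = s*a + d*(q - p); solve the scale s so the
    # founder variance of the breeding values equals sigma2_a exactly
    u = wa @ a
    v = wa @ (d * (1.0 - 2.0 * p))
    vu = u[founder_rows].var()
    cuv = np.cov(u[founder_rows], v[founder_rows], ddof=0)[0, 1]
    vv = v[founder_rows].var()
    if cfg.sigma2_a == 0.0 and vv == 0.0:
        add_score = np.zeros_like(u)
        a = np.zeros_like(a)
    else:
        disc = cuv ** 2 - vu * (vv - cfg.sigma2_a)
        if vu == 0.0 or disc < 0.0:
            raise ValueError(
                "sigma2_a below the additive variance induced by the dominance "
                "effects at these allele frequencies; increase sigma2_a or n_qtl")
        s = (-cuv + np.sqrt(disc)) / vu
        a *= s
        add_score = s * u + v

    tbv = add_score - add_score[founder_rows].mean()
    tdd = dom_score - dom_score[founder_rows].mean()
    truth.tbv = pd.Series(tbv, index=genotypes.ids)
    truth.tdd = pd.Series(tdd, index=genotypes.ids)
    truth.qtl_effects = pd.DataFrame(
        {"a": a, "d": d}, index=[genotypes.markers[j] for j in qtl_cols])

    progeny = [i for i in genotypes.ids if i in truth.family_of]
    families = sorted({truth.family_of[i] for i in progeny})
    trial_of_family = {fam: f"S{(k % cfg.n_trials) + 1}" for k, fam in enumerate(families)}
    trial_effects = {f"S{t + 1}": rng.normal(0.0, cfg.trial_effect_sd)
                     for t in range(cfg.n_trials)}
    rows = []
    for i in progeny:
        trial = trial_of_family[truth.family_of[i]]
        y = (truth.tbv[i] + truth.tdd[i] + trial_effects[trial]
             + rng.normal(0.0, np.sqrt(cfg.sigma2_e)))
        rows.append((i, trial, "R1", y))
    return pd.DataFrame(rows, columns=["id", "trial", "replicate", "trait"])


def inject_pedigree_errors(truth: SimulationTruth, error_rate: float,
                           seed: int) -> SimulationTruth:
    """Corrupt a fraction of CP progeny records in the documented pedigree.

    For each selected CP progeny the documented sire or dam (coin flip)
    is replaced by a random founder that is not a true parent.  The error
    list is retained in the returned truth.  ``error_rate=0`` returns an
    identical documented pedigree.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    doc = truth.documented_pedigree
    founders = truth.true_pedigree.founders
    cp = [i for i in doc.ids if truth.mating_type_of.get(i) == "CP"]
    n_err = int(round(error_rate * len(cp)))
    chosen = list(rng.choice(cp, size=n_err, replace=False)) if n_err else []
    df = doc.to_frame().set_index("id")
    errors = []
    for child in chosen:
        which = "sire" if rng.random() < 0.5 else "dam"
        true_s, true_d = truth.true_pedigree.parents_of(child)
        candidates = [f for f in founders if f not in (true_s, true_d)]
        wrong = rng.choice(candidates)
        errors.append({"id": child, "field": which,
                       "documented": df.loc[child, which], "replaced_by": wrong})
        df.loc[child, which] = wrong
    df = df.reset_index()
    new_doc = Pedigree(df["id"], df["sire"], df["dam"],
                       family=doc.family, mating_type=doc.mating_type)
    return replace(truth, documented_pedigree=new_doc, errors=errors)


def simulate_population(cfg: SimConfig):
    """Founders -> pedigree/genotypes -> traits in one call.

    Returns ``(truth, genotypes, traits)``.
    """
    founders = simulate_founders(cfg)
    truth, genotypes = simulate_pedigree_and_genotypes(founders, cfg)
    traits = simulate_traits(genotypes, truth, cfg)
    return truth, genotypes, traits
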