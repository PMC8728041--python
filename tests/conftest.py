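"""Shared fixtures: toy pedigrees, simulated populations, Monte-Carlo oracles."""

import numpy as np
import pytest

from treeblup import (SimConfig, simulate_population, standardize_traits,
                      filter_markers, impute_mean, grm_vanraden, grm_dominance)
from treeblup.io import Pedigree


# ---------------------------------------------------------------------------
# Independent oracle: gene-dropping kinship
# ---------------------------------------------------------------------------

def gene_drop_relationship(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Additive relationship matrix estimated by Monte-Carlo gene dropping.

    Founders receive unique allele labels; each offspring inherits one
    random allele per parent per replicate drop.  The relationship is
    twice the probability that randomly drawn alleles from two
    individuals are identical by descent; the diagonal is 1 + F with
    F the IBD probability of an individual's own two alleles.
    Independent of the tabular A-matrix recursion it is used to check.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    al = np.empty((n, 2, n_drops), dtype=np.int32)
    next_label = 0
    cols = np.arange(n_drops)
    for k in range(n):
        for slot, par in enumerate((ped.sire_idx[k], ped.dam_idx[k])):
            if par < 0:
                al[k, slot, :] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                al[k, slot, :] = al[par, pick, cols]
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            m = ((al[i, 0] == al[j, 0]).mean() + (al[i, 0] == al[j, 1]).mean()
                 + (al[i, 1] == al[j, 0]).mean() + (al[i, 1] == al[j, 1]).mean())
            phi = m / 4.0
            if i == j:
                f = (al[i, 0] == al[i, 1]).mean()
                a[i, i] = 1.0 + f
            else:
                a[i, j] = a[j, i] = 2.0 * phi
    return a


def random_pedigree(n: int, n_founders: int, seed: int) -> Pedigree:
    """A random acyclic pedigree: each non-founder mates two earlier ids."""
    rng = np.random.default_rng(seed)
    ids = [f"I{k}" for k in range(n)]
    sires, dams = [], []
    for k in range(n):
        if k < n_founders:
            sires.append("0")
            dams.append("0")
        else:
            s, d = rng.integers(0, k, size=2)
            sires.append(ids[s])
            dams.append(ids[d])
    return Pedigree(ids, sires, dams)


# ---------------------------------------------------------------------------
# Toy pedigrees
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def fullsib_pedigree():
    """Two unrelated parents, two full sibs, one offspring of the sibs."""
    return Pedigree(["s", "d", "x", "y", "z"],
                    ["0", "0", "s", "s", "x"],
                    ["0", "0", "d", "d", "y"])


# ---------------------------------------------------------------------------
# Simulated populations (module-expensive, shared session-wide)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pop_additive():
    """Clean additive CP population: h2 = 0.35, no dominance, no selfing."""
    cfg = SimConfig(n_founders=150, n_markers=800, n_qtl=800, sigma2_a=0.35,
                    sigma2_d=0.0, sigma2_e=0.65, selfing_rate=0.0,
                    family_plan=[("CP", 10)] * 40, seed=21)
    truth, geno, traits = simulate_population(cfg)
    gi = impute_mean(filter_markers(geno))
    return {
        "cfg": cfg, "truth": truth, "geno": geno, "geno_imputed": gi,
        "traits": standardize_traits(traits), "grm": grm_vanraden(gi),
    }


@pytest.fixture(scope="session")
def pop_dominance():
    """OP/CP/polymix population with selfing and directional dominance."""
    cfg = SimConfig(n_founders=150, n_markers=1200, n_qtl=300,
                    sigma2_a=0.2, sigma2_d=0.15, sigma2_e=0.65,
                    dominance_direction=1.0, selfing_rate=0.3,
                    family_plan=[("OP", 12)] * 30 + [("CP", 12)] * 10
                                + [("POLYMIX", 12)] * 10,
                    seed=17)
    truth, geno, traits = simulate_population(cfg)
    gi = impute_mean(filter_markers(geno))
    return {
        "cfg": cfg, "truth": truth, "geno": geno, "geno_imputed": gi,
        "traits": standardize_traits(traits), "grm": grm_vanraden(gi),
        "grm_dom": grm_dominance(gi),
    }
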