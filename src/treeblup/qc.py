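"""Marker quality control, mean imputation, het-based inbreeding, trait scaling.

The QC order mirrors the evaluation pipeline: markers are filtered on
observed calls (call rate, minor-allele frequency), then missing calls are
mean-imputed, and allele frequencies are computed once on the filtered
panel over the full genotyped sample and reused by every downstream
matrix.  Method-of-moments inbreeding coefficients use the excess of
observed over expected homozygous calls per individual, with the small
sample bias correction 2N/(2N-1) on the expected heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, trait_columns

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_in: int
    n_out: int
    removed_call_rate: int
    removed_maf: int


class EmptyPanelError(ValueError):
    """All markers were removed by filtering."""


def filter_markers(g: GenotypeMatrix, min_call_rate: float = 0.90,
                   min_maf: float = 0.01, return_report: bool = False):
    """Drop markers with call rate below *min_call_rate* or MAF below *min_maf*.

    Markers exactly at a threshold are retained.  Returns the filtered
    matrix (and a :class:`FilterReport` when *return_report* is true).
    """
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    cr_ok = g.call_rate >= min_call_rate
    maf_ok = g.maf >= min_maf
    keep = cr_ok & maf_ok
    if not keep.any():
        raise EmptyPanelError("all markers removed by QC filters")
    report = FilterReport(
        n_in=g.n_markers, n_out=int(keep.sum()),
        removed_call_rate=int((~cr_ok).sum()),
        removed_maf=int((cr_ok & ~maf_ok).sum()))
    log.info("marker QC: %d -> %d (call rate removed %d, MAF removed %d)",
             report.n_in, report.n_out, report.removed_call_rate, report.removed_maf)
    out = g.subset(markers=[m for m, k in zip(g.markers, keep) if k])
    return (out, report) if return_report else out


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its marker's mean observed genotype (2p)."""
    calls = g.calls.copy()
    n_obs = (~np.isnan(calls)).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"marker {g.markers[j]!r} has no observed calls")
    col_mean = np.nanmean(calls, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(calls))
    calls[nan_r, nan_c] = col_mean[nan_c]
    return GenotypeMatrix(g.ids, g.markers, calls)


def inbreeding_het(g: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments inbreeding from observed vs expected homozygosity.

    For individual i, over its non-missing markers:
    ``F_i = (O_hom - E_hom) / (M_i - E_hom)`` where
    ``E_hom = sum_j [1 - 2 p_j q_j * 2N/(2N-1)]`` and N is the number of
    individuals the allele frequencies were computed on.  Fully homozygous
    individuals get F = 1 regardless of the frequency estimates.

    Returns a DataFrame indexed by id with columns
    ``O_hom, E_hom, M, F`` (F is NaN-flagged when ``M == E_hom``).
    """
    calls = g.calls
    if not np.isin(calls[~np.isnan(calls)], (0.0, 1.0, 2.0)).all():
        raise ValueError("inbreeding_het requires raw 0/1/2 calls (before imputation)")
    n = g.n_individuals
    p = g.p
    bias = (2.0 * n) / (2.0 * n - 1.0)
    exp_hom_j = 1.0 - 2.0 * p * (1.0 - p) * bias  # per-marker expected hom.
    obs = ~np.isnan(calls)
    m_i = obs.sum(axis=1).astype(float)
    o_hom = (obs & (calls != 1.0)).sum(axis=1).astype(float)
    e_hom = obs @ exp_hom_j
    denom = m_i - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    if np.isnan(f).any():
        log.warning("inbreeding_het: %d individuals with degenerate M == E_hom",
                    int(np.isnan(f).sum()))
    return pd.DataFrame({"O_hom": o_hom, "E_hom": e_hom, "M": m_i, "F": f},
                        index=pd.Index(g.ids, name="id"))


def standardize_traits(traits: pd.DataFrame, by: str = "trial") -> pd.DataFrame:
    """Standardize each trait to zero mean / unit SD within each level of *by*.

    Accounts for scale differences between trials (e.g. measurement age);
    missing values propagate unchanged.
    """
    out = traits.copy()
    for col in trait_columns(out):
        vals = out[col].astype(float)
        grouped = vals.groupby(out[by])
        mean = grouped.transform("mean")
        sd = grouped.transform("std", ddof=1)
        counts = grouped.transform("count")
        if (counts < 2)[vals.notna()].any():
            raise ValueError(f"trait {col!r}: a {by} level has <2 non-missing values")
        if (sd[vals.notna()] == 0).any():
            raise ValueError(f"trait {col!r}: zero within-{by} variance")
        out[col] = (vals - mean) / sd
    return out
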