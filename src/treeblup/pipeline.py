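"""End-to-end genomic evaluation: QC -> matrices -> REML fits -> CV -> tables.

``run_all`` drives the whole analysis from one configuration, either on
files (pedigree, genotypes, traits, optional imported IBD matrix) or on
a freshly simulated population, and emits the standard result tables:

* genetic parameters (variance components, h2, d2, AIC) per model on the
  genotyped trees, and for single-step/pedigree models on all trees;
* relationship-matrix dispersion statistics;
* theoretical accuracies grouped as parents / genotyped progeny /
  nongenotyped progeny;
* cross-validated predictive ability and prediction accuracy with
  Tukey grouping letters;
* inbreeding-depression regression and dominance/inbreeding correlation;
* the parentage report and corrected pedigree.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, qc, relmat, pedcheck, validation, inbreeding as inb
from .mixedmodel import ModelSpec, reml_fit, theoretical_accuracy
from .simulate import SimConfig, simulate_population

log = logging.getLogger(__name__)

DEFAULT_MODELS = ["ABLUP", "ABLUP-PR", "GBLUP-A", "GBLUP-AD", "ssGBLUP"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    # data source: either simulate (SimConfig kwargs) or file paths
    simulate: dict | None = None
    pedigree: str | None = None
    genotypes: str | None = None
    genotype_dialect: str = "csv"
    traits_file: str | None = None
    ibd_matrix: str | None = None      # imported, externally computed IBD GRM

    trait: str = "trait"
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    kfold: int = 10
    seed: int = 0
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    confirm_min: float = pedcheck.CONFIRM_MIN
    blend_weight: float = 0.95
    rescale_ibd: bool = True
    # which simulated individuals count as "genotyped" for the single-step path
    genotyped_progeny_per_family: int = 5
    genotyped_parent_fraction: float = 0.77
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(cfg: RunConfig):
    """Return (documented pedigree, genotypes, traits, truth-or-None)."""
    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
        truth, genotypes, traits = simulate_population(sim)
        return truth.documented_pedigree, genotypes, traits, truth
    ped = io.read_pedigree(cfg.pedigree)
    genotypes = io.read_genotypes(cfg.genotypes, dialect=cfg.genotype_dialect)
    traits = io.read_traits(cfg.traits_file)
    return ped, genotypes, traits, None


def _select_genotyped(cfg: RunConfig, ped: io.Pedigree, genotypes: io.GenotypeMatrix,
                      traits: pd.DataFrame, rng: np.random.Generator):
    """The genotyped subset: all file ids, or a study-like sample when simulating."""
    if cfg.simulate is None:
        return [i for i in genotypes.ids]
    parents = sorted(ped.parent_ids)
    n_gp = int(round(cfg.genotyped_parent_fraction * len(parents)))
    geno_parents = sorted(rng.choice(parents, size=n_gp, replace=False))
    fam_of = ped.family
    by_fam: dict[str, list[str]] = {}
    phenotyped = set(traits["id"].astype(str))
    for i in ped.ids:
        if i in fam_of and i in phenotyped:
            by_fam.setdefault(fam_of[i], []).append(i)
    geno_prog = []
    for fam in sorted(by_fam):
        members = by_fam[fam]
        k = min(cfg.genotyped_progeny_per_family, len(members))
        geno_prog.extend(sorted(rng.choice(members, size=k, replace=False)))
    return geno_parents + geno_prog


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_all(cfg: RunConfig) -> dict:
    """Run the full evaluation; returns a dict of result tables.

    When ``cfg.out_dir`` is set every table is also written as CSV.
    """
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, object] = {}

    t0 = _stage("load/simulate inputs")
    ped_doc, genotypes_raw, traits_raw, truth = _load_inputs(cfg)

    _stage("marker QC and imputation")
    geno_ids = _select_genotyped(cfg, ped_doc, genotypes_raw, traits_raw, rng)
    graw = genotypes_raw.subset(ids=geno_ids)
    gfilt, qc_report = qc.filter_markers(graw, cfg.min_call_rate, cfg.min_maf,
                                         return_report=True)
    f_table = qc.inbreeding_het(gfilt)
    gimp = qc.impute_mean(gfilt)
    out["qc"] = pd.DataFrame([vars(qc_report)])
    out["inbreeding_coefficients"] = f_table.reset_index()

    _stage("trait standardization")
    traits = qc.standardize_traits(traits_raw)
    trait = cfg.trait

    _stage("genomic relationship matrices")
    g_a = relmat.grm_vanraden(gimp)
    g_d = relmat.grm_dominance(gimp)
    g_ibd = io.read_matrix(cfg.ibd_matrix, kind="G_IBD") if cfg.ibd_matrix else None
    disp = {"G_A": relmat.dispersion_stats(g_a)}
    if g_ibd is not None:
        disp["G_IBD"] = relmat.dispersion_stats(g_ibd)
    out["grm_dispersion"] = pd.DataFrame(disp).rename_axis("statistic").reset_index()

    _stage("pedigree verification and polymix assignment")
    report = pedcheck.verify_parentage(g_a, ped_doc, cfg.confirm_min)
    pools = truth.pools if truth is not None else {}
    if pools:
        pools_geno = {f: p for f, p in pools.items()
                      if all(c in set(g_a.ids) for c in p)}
        poly = pedcheck.assign_polymix_fathers(g_a, ped_doc, pools_geno,
                                               cfg.confirm_min)
        report.assignments = poly.assignments
        report.summary.update(poly.summary)
    ped_corr = pedcheck.corrected_pedigree(ped_doc, report)
    out["parentage_records"] = report.records
    out["parentage_assignments"] = report.assignments
    out["parentage_summary"] = pd.DataFrame([report.summary])

    _stage("pedigree matrices")
    a_doc = relmat.amatrix(ped_doc)
    a_corr = relmat.amatrix(ped_corr)

    phenotyped = traits["id"].astype(str)
    geno_phen = [i for i in geno_ids if i in set(phenotyped)]
    traits_geno = traits[traits["id"].isin(set(geno_phen))]

    # ------------------------------------------------------------------ fits
    _stage("REML fits on genotyped trees")
    specs: dict[str, ModelSpec] = {}
    for m in cfg.models:
        if m == "ABLUP":
            specs[m] = ModelSpec(trait, [("additive", a_doc)], label=m)
            specs["ABLUP-AD"] = ModelSpec(
                trait, [("additive", a_doc),
                        ("dominance", relmat.dmatrix_pedigree(ped_doc, a_doc))],
                label="ABLUP-AD")
        elif m == "ABLUP-PR":
            specs[m] = ModelSpec(trait, [("additive", a_corr)], label=m)
        elif m == "GBLUP-A":
            specs[m] = ModelSpec(trait, [("additive", g_a)], label=m)
        elif m == "GBLUP-AD":
            specs[m] = ModelSpec(
                trait, [("additive", g_a), ("dominance", g_d)], label=m)
        elif m == "GBLUP-IBD":
            if g_ibd is None:
                raise ValueError("GBLUP-IBD requested without an ibd_matrix file")
            specs[m] = ModelSpec(trait, [("additive", g_ibd)], label=m)
        elif m in ("ssGBLUP", "ssGBLUP-IBD"):
            continue  # handled on all trees below
        else:
            raise ValueError(f"unknown model {m!r}")
    fits = {}
    rows = []
    for label, spec in specs.items():
        fit = reml_fit(spec, traits_geno)
        fits[label] = fit
        row = {"model": label, "additive": fit.varcomp.get("additive", np.nan),
               "additive_se": fit.varcomp_se.get("additive", np.nan),
               "dominance": fit.varcomp.get("dominance", np.nan),
               "dominance_se": fit.varcomp_se.get("dominance", np.nan),
               "residual": fit.varcomp["residual"],
               "residual_se": fit.varcomp_se["residual"],
               "h2": fit.h2, "h2_se": fit.h2_se, "d2": fit.d2, "d2_se": fit.d2_se,
               "AIC": fit.aic, "converged": fit.converged}
        rows.append(row)
    out["genetic_parameters_genotyped"] = pd.DataFrame(rows)

    # ------------------------------------------------- single-step, all trees
    ss_models = [m for m in cfg.models if m.startswith("ssGBLUP")] or []
    ss_fits = {}
    if ss_models or "ABLUP" in cfg.models:
        _stage("single-step H-matrix and all-tree fits")
        rows = []
        all_specs = {}
        for m in ss_models:
            g_for_h = g_ibd if m == "ssGBLUP-IBD" else g_a
            rescale = True if m != "ssGBLUP-IBD" else cfg.rescale_ibd
            h = relmat.make_hmatrix(ped_corr, g_for_h, w=cfg.blend_weight,
                                    rescale=rescale)
            all_specs[m] = ModelSpec(trait, [("additive", h)], label=m)
        if "ABLUP" in cfg.models:
            all_specs["ABLUP-all"] = ModelSpec(trait, [("additive", a_doc)],
                                               label="ABLUP-all")
        if "ABLUP-PR" in cfg.models:
            all_specs["ABLUP-PR-all"] = ModelSpec(trait, [("additive", a_corr)],
                                                  label="ABLUP-PR-all")
        for label, spec in all_specs.items():
            fit = reml_fit(spec, traits)
            ss_fits[label] = fit
            rows.append({"model": label, "additive": fit.varcomp["additive"],
                         "additive_se": fit.varcomp_se["additive"],
                         "residual": fit.varcomp["residual"],
                         "residual_se": fit.varcomp_se["residual"],
                         "h2": fit.h2, "h2_se": fit.h2_se, "AIC": fit.aic,
                         "converged": fit.converged})
        out["genetic_parameters_all"] = pd.DataFrame(rows)

        _stage("theoretical accuracies by group")
        parents = set(ped_corr.parent_ids)
        geno_set = set(geno_ids)
        groups = {
            "parents": sorted(parents & set(ped_corr.ids)),
            "genotyped": sorted((geno_set - parents) & set(ped_corr.ids)),
            "nongenotyped": sorted(set(ped_corr.ids) - parents - geno_set),
        }
        f_ped = relmat.inbreeding_from_pedigree(ped_corr)
        acc_rows = []
        for label, fit in ss_fits.items():
            s2a = fit.varcomp["additive"]
            for gname, members in groups.items():
                members = [i for i in members if i in fit.pev.index]
                if not members:
                    continue
                r = theoretical_accuracy(
                    fit.pev.loc[members].to_numpy(), s2a,
                    np.array([f_ped[i] for i in members]))
                acc_rows.append({"model": label, "group": gname,
                                 "n": len(members), "accuracy": float(r.mean())})
        out["theoretical_accuracy"] = pd.DataFrame(acc_rows)

    # --------------------------------------------------------------------- CV
    _stage("cross-validation (genotyped trees)")
    cv_results = []
    folds = validation.kfold_split(geno_phen, k=cfg.kfold, seed=cfg.seed)
    for label, spec in specs.items():
        kind = "genotypic" if label.endswith("AD") else "additive"
        cv = validation.cross_validate(spec, traits_geno, k=cfg.kfold,
                                       seed=cfg.seed, eval_ids=geno_phen,
                                       prediction_kind=kind, folds=folds)
        cv_results.append(cv)
    out["cv_per_fold"] = pd.concat(
        [r.per_fold.assign(model=r.label) for r in cv_results], ignore_index=True)
    out["cv_summary"] = pd.DataFrame(
        [{"model": r.label, "predictive_ability": r.predictive_ability,
          "predictive_ability_sd": r.predictive_ability_sd,
          "prediction_accuracy": r.prediction_accuracy,
          "prediction_accuracy_sd": r.prediction_accuracy_sd}
         for r in cv_results])
    if len(cv_results) >= 2:
        out["cv_comparison_pa"] = validation.compare_models(
            cv_results, metric="predictive_ability")
        out["cv_comparison_acc"] = validation.compare_models(
            cv_results, metric="prediction_accuracy")

    # ------------------------------------------------------------- inbreeding
    _stage("inbreeding-depression analysis")
    fvec = f_table["F"]
    tr = traits.set_index("id")[trait]
    shared = [i for i in fvec.index if i in tr.index]
    dep = inb.depression_regression(tr.loc[shared], fvec.loc[shared])
    dep_df = dep.to_frame()
    dep_df["flag"] = dep_df["p"].map(inb.significance_flag)
    if "GBLUP-AD" in fits:
        dd = fits["GBLUP-AD"].blup["dominance"]
        shared_d = [i for i in fvec.index if i in dd.index]
        r, p = inb.dominance_F_correlation(dd.loc[shared_d], fvec.loc[shared_d])
        dep_df = pd.concat([dep_df, pd.DataFrame(
            [{"term": "dominance_F_correlation", "estimate": r, "statistic": r,
              "p": p, "flag": inb.significance_flag(p)}])], ignore_index=True)
    out["inbreeding_depression"] = dep_df

    out["_fits"] = fits
    out["_ss_fits"] = ss_fits
    out["_truth"] = truth
    out["_corrected_pedigree"] = ped_corr

    if cfg.out_dir:
        outdir = Path(cfg.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in out.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.csv", index=False)
        io.write_pedigree(ped_corr, outdir / "corrected_pedigree.csv")
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return out
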