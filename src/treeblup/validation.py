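"""K-fold cross-validation: predictive ability, prediction accuracy, model tests.

Predictive ability is the Pearson correlation between cross-validated
predictions and the adjusted phenotypes of the test fold; prediction
accuracy correlates the same predictions with the *same model's*
full-data estimated values (the full-data benchmark captures hidden and
within-family relationships that a pedigree benchmark misses).  Models
are compared by one-way ANOVA on fold-level values followed by Tukey's
honest-significant-difference grouping letters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .mixedmodel import ConvergenceWarning, ModelSpec, reml_fit

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    label: str
    folds: dict[str, int]                  # id -> fold
    per_fold: pd.DataFrame                 # fold, predictive_ability, prediction_accuracy
    predictive_ability: float = field(init=False)
    prediction_accuracy: float = field(init=False)
    predictive_ability_sd: float = field(init=False)
    prediction_accuracy_sd: float = field(init=False)

    def __post_init__(self):
        ok = self.per_fold[self.per_fold["converged"]]
        self.predictive_ability = float(ok["predictive_ability"].mean())
        self.prediction_accuracy = float(ok["prediction_accuracy"].mean())
        self.predictive_ability_sd = float(ok["predictive_ability"].std(ddof=1))
        self.prediction_accuracy_sd = float(ok["prediction_accuracy"].std(ddof=1))


def _safe_corr(a, b) -> float:
    """Pearson r, with 0 for degenerate (constant) inputs: no information."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() < 1e-12 or b.std() < 1e-12:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def kfold_split(ids, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Random folds of size differing by at most one; deterministic by seed."""
    ids = [str(i) for i in ids]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError("fewer ids than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[p]: int(f % k) for f, p in enumerate(perm)}


def cross_validate(spec: ModelSpec, traits: pd.DataFrame, k: int = 10,
                   seed: int = 0, eval_ids=None, prediction_kind: str = "additive",
                   folds: dict[str, int] | None = None) -> CVResult:
    """K-fold cross-validation of one model.

    *eval_ids* restricts the evaluation set (e.g. to the genotyped trees
    in a single-step model); folds are drawn within it.  Per fold the
    model is refitted on the remaining records and the left-out
    individuals are predicted through the relationship matrices without
    their phenotypes.  Non-convergent folds are flagged and excluded
    from the means.
    """
    df = traits.copy()
    df["id"] = df["id"].astype(str)
    if eval_ids is None:
        eval_ids = df["id"].tolist()
    eval_ids = [str(i) for i in eval_ids if str(i) in set(df["id"])]
    if folds is None:
        folds = kfold_split(eval_ids, k=k, seed=seed)

    full = reml_fit(spec, df)
    bench = pd.Series(full.model.predict(eval_ids, kind=prediction_kind),
                      index=eval_ids)
    pheno = df.set_index("id")[spec.response].astype(float)

    rows = []
    for f in sorted(set(folds.values())):
        test = [i for i, ff in folds.items() if ff == f]
        train = df[~df["id"].isin(set(test))]
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                fit = reml_fit(spec, train)
            preds = pd.Series(fit.model.predict(test, kind=prediction_kind), index=test)
            pa = _safe_corr(preds, pheno.loc[test])
            acc = _safe_corr(preds, bench.loc[test])
        except (ConvergenceWarning, Warning, np.linalg.LinAlgError) as e:
            log.warning("fold %d non-convergent (%s); excluded from means", f, e)
            converged, pa, acc = False, np.nan, np.nan
        rows.append({"fold": f, "predictive_ability": pa,
                     "prediction_accuracy": acc, "converged": converged})
    per_fold = pd.DataFrame(rows)
    return CVResult(label=spec.label or spec.response, folds=folds, per_fold=per_fold)


def _letter_display(labels: list[str], means: pd.Series, reject: dict) -> dict[str, str]:
    """Compact letter display: models sharing a letter do not differ."""
    order = list(means.sort_values(ascending=False).index)
    letters = {m: "" for m in labels}
    groups: list[set[str]] = []
    for m in order:
        placed = False
        for grp in groups:
            if all(not reject[frozenset((m, o))] for o in grp if o != m):
                grp.add(m)
                placed = True
        if not placed:
            groups.append({m})
    # merge-proof assignment: one letter per group in mean order
    for gi, grp in enumerate(groups):
        for m in grp:
            letters[m] += chr(ord("a") + gi)
    return {m: "".join(sorted(set(v))) for m, v in letters.items()}


def compare_models(results: list[CVResult], metric: str = "predictive_ability",
                   alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + Tukey HSD grouping of fold-level values across models.

    Returns one row per model with its mean, SD and group letter; models
    sharing a letter are not significantly different at *alpha*.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    ks = {len(r.per_fold) for r in results}
    if len(ks) != 1:
        raise ValueError("models were cross-validated with different k")
    if ks.pop() < 3:
        raise ValueError("need k >= 3 folds for a residual df")
    long = pd.concat(
        [pd.DataFrame({"model": r.label,
                       "value": r.per_fold.loc[r.per_fold["converged"], metric]})
         for r in results], ignore_index=True)
    groups = [g["value"].to_numpy() for _, g in long.groupby("model")]
    f_stat, p_anova = stats.f_oneway(*groups)
    tuk = pairwise_tukeyhsd(long["value"], long["model"], alpha=alpha)
    summ = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    reject = {frozenset((str(r["group1"]), str(r["group2"]))): bool(r["reject"])
              for _, r in summ.iterrows()}
    means = long.groupby("model")["value"].mean()
    sds = long.groupby("model")["value"].std(ddof=1)
    letters = _letter_display(list(means.index), means, reject)
    out = pd.DataFrame({
        "model": means.index, "mean": means.values,
        "sd": sds.reindex(means.index).values,
        "group": [letters[m] for m in means.index]})
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p_anova)
    out.attrs["tukey"] = summ
    return out.sort_values("mean", ascending=False).reset_index(drop=True)
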