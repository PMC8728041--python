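# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical choices, and the limitations of `treeblup`.

## The individual-tree mixed model

Every evaluation is a linear mixed model over individual trees,

y = Xμ + Σ_k Z_k u_k + ε,  u_k ~ N(0, K_k σ²_k),  ε ~ N(0, I σ²_ε),

with one phenotype record per tree (trait tables are standardized to
zero mean and unit variance within each trial first, which removes
trial means and age-driven scale differences). The fixed part is an
intercept by default; covariates such as the individual inbreeding
coefficient F can be added (the "inbreeding as fixed covariate"
experiment, which absorbs mean directional dominance).

The covariance kernels K_k define the model family:

| model    | additive kernel              | dominance kernel |
|----------|------------------------------|------------------|
| ABLUP    | pedigree A (tabular, with F) | pedigree D       |
| GBLUP    | VanRaden G_A, or imported IBD matrix | Vitezica G_D |
| ssGBLUP  | combined H                   | —                |

**Pedigree A.** Tabular recursion with inbreeding: a_ii = 1 + F_i,
F_i = ½·a_{sire,dam}; a_ij = ½(a_{j,sire(i)} + a_{j,dam(i)}); unknown
parents contribute zero (founders are taken unrelated and non-inbred,
which matches how OP and polymix fathers are recorded). Exact, no
approximation.

**Pedigree D.** Classical dominance relationship
d_ij = ¼(a_{s(i)s(j)} a_{d(i)d(j)} + a_{s(i)d(j)} a_{d(i)s(j)}) with a
unit diagonal. The recursion ignores inbreeding in the dominance
covariance — a known limitation of the classical formula, accepted here
deliberately; the genomic G_D is the preferred dominance kernel.

**Genomic G_A.** VanRaden method 1, W_a = X − 2p with X the 0/1/2
genotype matrix, denominator 2 Σ p_j q_j. Allele frequencies are
estimated once from the analyzed (filtered, full genotyped) sample and
reused everywhere, because no base-population frequencies are
available; consequently mean(G_A) ≈ 0 by construction.

**Genomic G_D.** Zero-mean dominance coding
{0, 1, 2} → {−2p², 2pq, −2q²}, denominator Σ (2 p_j q_j)². This is the
orientation whose per-marker HWE variance is exactly (2pq)², making
E[diag(G_D)] = 1 in an outbred population; the matrix is invariant to
which allele is counted. Mean-imputed fractional genotypes enter both
codings by linear interpolation between the three genotype states.

**Single-step H.** With individuals partitioned into nongenotyped (1)
and genotyped (2) blocks of A:

1. rescale G to the pedigree scale: G_a = βG + α where β and α solve
   Avg.diag(G)β + α = Avg.diag(A22) and Avg.offdiag(G)β + α =
   Avg.offdiag(A22);
2. blend G_w = w·G_a + (1−w)·A22 with w = 0.95 (keeps G_w invertible);
   if the blend is still not positive definite, eigenvalues are floored
   at 1e-6 with a logged warning;
3. assemble H11 = A11 + A12 A22⁻¹ (G_w − A22) A22⁻¹ A21,
   H12 = A12 A22⁻¹ G_w, H22 = G_w.

Imported IBD matrices can either go through the same rescaling or skip
it (`rescale=False`); the default is to rescale, since an IBD matrix
estimated without the pedigree has no guaranteed scale agreement with
A22 either. Matrix id order is nongenotyped block first, then
genotyped, stable within each block by input order.

## REML

Variance components maximize the restricted log-likelihood

logL = −½ [log|V| + log|X'V⁻¹X| + y'Py],
V = Σ_k σ²_k Z_k K_k Z_k' + I σ²_ε,

by Newton–Raphson with **direct inversion** of the n×n covariance and
the **average-information** approximation to the Hessian
(AI_kl = ½ y'P V_k P V_l P y), stabilized by step-halving whenever a
step would decrease logL. Numerical choices:

* initialization: every component (including the residual) starts at
  0.5·var(y)/(n_terms + 1) — scale-aware and neutral;
* components are constrained ≥ 1e-8 by projection; a component at the
  floor with an inward-pointing score is frozen for that iteration, so
  boundary solutions (e.g. null data) terminate cleanly;
* convergence when the relative logL change < 1e-8 or the largest
  parameter change < 1e-6; non-convergence in `max_iter` (default 100)
  returns a flagged fit with partial results and a warning;
* standard errors are from the inverse average-information matrix at
  the optimum; h² and d² standard errors follow by the delta method
  (the SE method is a documented choice — several are in use in the
  field);
* AIC = −2 logL_reml + 2·(number of variance components, residual
  included). Only AIC *differences* between models sharing the same
  fixed part are meaningful; absolute values depend on likelihood
  constants that differ between software.

**BLUP and PEV.** Random-effect solutions are computed for *all*
individuals present in each kernel, û_k = σ²_k K_k Z' P y, so
unphenotyped (cross-validation test, nongenotyped single-step) trees
are predicted through their covariance with the training set.
Prediction error variance of the additive effect uses the
mixed-model-equation identity Var(u − û) = σ²K − σ⁴ K Z' P Z K, which
avoids inverting K. Theoretical accuracy is
r_i = √(1 − PEV_i / (σ²_a (1 + F_i))) with pedigree F_i, clipped to
[0, 1] with a warning if the radicand is negative.

The estimator (`BLUPModel`) follows the scikit-learn protocol —
constructor parameters, `fit(ids, y)`, trailing-underscore fitted
attributes, `predict(ids, kind="additive"|"genotypic")` — and
`reml_fit`/`predict_unphenotyped` are thin functional wrappers.

## QC and inbreeding coefficients

Markers are filtered on observed calls (call rate ≥ 0.90 and MAF ≥ 0.01
by default; boundary values are retained, as strictness at the boundary
is a convention), *then* missing calls are mean-imputed (imputation
after filtering, because the filter criteria refer to observed calls).
Frequencies are computed once on the filtered panel over the full
genotyped set and reused by every matrix.

Method-of-moments inbreeding: F_i = (O_hom − E_hom)/(M_i − E_hom) with
E_hom = Σ_j [1 − 2 p_j q_j · 2N/(2N−1)] over markers non-missing in i.
The 2N/(2N−1) factor is the small-sample bias correction of the
classical excess-homozygosity estimator; fully homozygous individuals
get F = 1 under any frequency estimate. F requires raw 0/1/2 calls and
is therefore computed before imputation.

## Cross-validation and model comparison

K-fold (default 10) splits are drawn uniformly over individuals.
Per fold, the model is refitted with the test fold's phenotype records
removed (removal and NaN-masking are verified to give identical
predictions — no leakage), and the left-out trees are predicted through
the kernels. Predictive ability = Pearson r(prediction, phenotype) on
the test fold; prediction accuracy = Pearson r(prediction, full-data
estimate *from the same model*). Benchmarking against the model's own
full-data values rather than pedigree EBVs avoids penalizing genomic
models for capturing within-family (Mendelian-sampling) deviations a
shallow pedigree cannot represent. For single-step models the folds and
correlations are restricted to the genotyped subset. Fold-level values
feed a one-way ANOVA and Tukey HSD grouping letters at α = 0.05;
degenerate (constant) prediction vectors get a correlation of 0 (no
information) rather than NaN.

## Inbreeding depression

Trait values (standardized, adjusted) are regressed on the het-based F:
linear, then quadratic (F, F²), compared by a partial F-test with df
(1, n−3). For a single added regressor the partial F equals the square
of the quadratic coefficient's t statistic — asserted in the tests as
an exact identity. Two degenerate cases are handled explicitly: fewer
than three distinct F values make F² collinear (quadratic and partial-F
entries become NaN, mirroring the "–" cells such tables show), and a
numerically exact linear fit yields partial F = 0. The correlation of
GBLUP-AD dominance deviations with F measures how much of the dominance
signal is inbreeding depression; under directional dominance with
selfing it is strongly negative.

## Pedigree verification

A documented parent is confirmed when the genomic relationship with its
progeny is ≥ 0.30, flagged as an error when below, and unresolved when
the parent is not genotyped. The 0.30 floor operationalizes the usual
0.30–0.5 parent-offspring confirmation band; the upper end is not
enforced because parent-offspring coefficients legitimately exceed 0.5
under inbreeding. Polymix fathers are assigned per progeny as the
pollen-pool candidate with the maximal relationship, provided it clears
the same floor; ties break toward the candidate with the higher mean
relationship to the progeny's maternal half-sibs, then lexicographic id
(deterministic output). Families whose progeny all resolve to one sire
are reported as recovered full-sib families. Likelihood-based parentage
(trio likelihoods, genotyping-error models) is out of scope.

## The synthetic-data generator

The generator emulates a two-generation, multi-trial forest breeding
population: ~200 families mixing OP, CP and polymix matings from a
founder set of unrelated parents, thousands of unlinked biallelic
markers with founder MAF uniform on (0.05, 0.5), and one trait per run.

* **Founders** are drawn marker-wise from Hardy–Weinberg proportions.
* **Progeny** arise by Mendelian gene dropping (one transmitted allele
  per parent per marker, markers unlinked). OP matings self with
  probability `selfing_rate` (default 0.15 — OP eucalypt outcrossing
  rates are typically 75–90%, so a mid-range selfing fraction; the true
  rate is population-specific and exposed as a parameter), otherwise an
  outcross to a random other founder; CP matings have a recorded sire;
  polymix sires are drawn from a declared 5-candidate pollen pool and
  recorded as unknown, with pool membership retained. Selfing is the
  sole inbreeding mechanism, so pedigree F takes values {0, 0.5} in
  two generations; the *genomic* (het-based) F is continuous around
  those levels, which is what the depression regressions use.
* **Traits**: `n_qtl` markers act as QTL with genotypic additive
  effects a_j ~ N(0,1) and dominance effects d_j with half-normal
  magnitude and a fraction `dominance_direction` (default 1.0)
  positive. Effects are decomposed at founder allele frequencies into
  average effects α_j = a_j + d_j(q_j − p_j) and zero-mean dominance
  deviations, then rescaled so the realized founder-sample variances
  equal σ²_a and σ²_d *exactly* (this makes parameter-recovery targets
  well-posed). Phenotypes (progeny only) add a round-robin-by-family
  trial effect (6 trials, SD 0.5) and N(0, σ²_ε) noise.
* **Pedigree errors** can be injected into a fraction of CP records
  (documented sire or dam replaced by a random non-parent founder) with
  the error list retained for recovery tests.

Default variance targets are σ²_a = 0.20, σ²_d = 0.15, σ²_ε = 0.65 on
the standardized-trait scale — a moderately heritable growth-type trait
in the regime where dominance and inbreeding depression are detectable.

**What the generator does not emulate**: linkage and LD between markers
(markers are unlinked; the LD structure of a real preselected panel is
unknowable), multi-generation selection, spatial field autocorrelation
(trial effects are block constants; the spatial adjustment of real
trials is replaced by per-trial standardization), genotyping error, and
selection of which trees get genotyped beyond a per-family quota.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to LD decay or spatial
artifacts.

**Problem sizes.** Parameter-recovery runs use 100 CP families × 15
progeny (n = 1500 phenotyped) with 1000 markers, all causal
(n_qtl = n_markers), across 20 replicate seeds; with sparse causal
markers the marker-estimated relationships attenuate the additive
component — a property of GBLUP itself, not of the REML solver — so
recovery is tested under the model's own architecture. The end-to-end
pipeline run in `scripts/acceptance.py` uses 100 families × 12 progeny
(1200 progeny + 200 founders) with 1200 markers, 300 causal, and a
study-like genotyped subset (5 progeny per family plus 77% of parents).

## Known limitations

* Pedigree dominance D ignores inbreeding in its recursion (classical
  formula); prefer G_D when genotypes exist.
* Direct-inversion REML is O(n³) per iteration; populations beyond
  ~10⁴ phenotyped individuals need sparse or preconditioned methods
  that are out of scope here.
* Single-trait models only; no genotype-by-environment terms, no
  epistatic variance components (epistasis is inferred only from
  curvature of the depression regression), no Bayesian samplers.
* With strongly directional dominance plus selfing, the dominance
  kernel and the inbreeding axis overlap; GBLUP-AD can then shift
  variance from the additive to the dominance component unless F is
  added as a fixed covariate (the covariate in turn absorbs mean
  dominance — both behaviors are real properties of these models and
  are reproduced, not suppressed).
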