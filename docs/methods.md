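# Methods

`coxselect` implements a pipeline for building composite prognostic models
of long-horizon cancer survival — Cox proportional-hazards indices over
molecular marker scores plus clinico-pathological covariates — and for
assessing them honestly with nested cross-validation and a time-dependent
discrimination statistic. This note records the statistical model, the
conventions the implementation fixes where the procedure leaves freedom,
and what the synthetic cohorts do and do not emulate.

## The model and its evaluation statistic

Patient risk is summarized by the Cox linear predictor (prognostic index)

    PI_i = sum_j beta_j x_ij ,

with coefficients estimated by maximizing the Breslow partial likelihood.
Covariates enter **raw** — fluorescence marker scores on their native
0–255 scale, tumor size in cm, ordinal grades — with no standardization;
hazard ratios are therefore per unit of the measured quantity, and the
prognostic index is invariant in rank to any rescaling.

Discrimination is measured by the **average time-dependent AUCROC
(ATD-AUCROC)**: at the time t of every death in a test set, form a
staircase ROC curve from the prognostic index with

* cases = patients already dead of disease by t (cumulative cases),
* controls = patients still under observation beyond t (dynamic controls),
* patients censored at or before t excluded at that time point,

and average the per-time AUCs over all deaths. The staircase (empirical
step-function) area counts only strict case-over-control orderings; a half
credit for tied scores is precisely the trapezoidal correction the
staircase convention exists to avoid, so ties score 0 by default
(`ties="strict"`); `ties="half"` is provided for sensitivity analysis.
Deaths sharing a time each contribute one term (multiplicity preserved);
the last event time, with no controls remaining, is skipped and recorded
as not included. An increasing transform of the scores leaves the value
unchanged, and reversing score signs maps v to 1 − v when no compared pair
is tied.

## Selection procedure

Backward elimination is likelihood-driven: at each step, every remaining
variable is removed in turn, the leave-one-out Cox model is refit on the
training fold, and the variable whose removal leaves the highest log
partial likelihood (least contribution) is eliminated and pushed onto the
front of a nested-variable list. The size-m nested model is the first m
entries. Inside each outer iteration of a repeated 10-fold
cross-validation, an inner 10-fold loop runs this elimination, scores all
nested sizes on the inner test fold, and keeps the best size per fold.
From the ten inner reduced models X with inner scores h_X, sizes n_X and
usage indicators U_X(v):

    expected size   <n> = sum_X h_X n_X / sum_X h_X
    stability       <v> = sum_X h_X U_X(v) / sum_X h_X .

The outer iteration trains the round(<n>) most stable variables on the
outer training set and scores this reduced model and the all-variable full
model on the untouched outer fold (both also on the training side, as an
overfitting diagnostic). Across repeats × outer folds the package reports
the score distributions, the reduced-size distribution, frequency-based
and ATD-weighted stability per variable, and a final model whose size is
the rounded mean outer reduced size and whose membership is the top
variables by frequency stability.

### Conventions fixed by this implementation

The procedure's description leaves several small choices open; these are
the ones coded, all deterministic:

* **Ties in event times**: Breslow approximation (shared risk-set
  denominator; patients censored at t stay in the risk set at t).
* **Likelihood ties during elimination**: remove the variable latest in
  the declared variable order.
* **Score ties when picking the best nested size**: prefer the smaller
  model (parsimony).
* **Rounding of <n>**: nearest integer, half away from zero, floored at 1
  and capped at the variable count.
* **Stability ties at the cut rank**: broken by the weighted stability,
  then declared order.
* **Final-model size**: rounded mean of outer reduced sizes (the full size
  distribution is reported alongside, since a mode- or median-based
  aggregation is equally defensible).
* **Non-convergent fits**: a candidate whose fit fails (constant column,
  separation, iteration cap) is treated as likelihood −∞ and never kept;
  an outer fold whose reduced/full fit fails is skipped and logged, and a
  run aborts if more than 20% of folds are lost.
* **Fold balance**: folds are stratified by the event indicator, so
  per-fold death counts differ by at most one within each repeat.
* **Randomness**: one master seed; per-repeat fold seeds derive from it
  via `numpy.random.SeedSequence.spawn`. Nothing else draws random
  numbers, so a summary is bit-reproducible given (cohort, variables,
  repeats, seed).

## Cox solver

The nested procedure refits on the order of 10^5–10^6 Cox models per run
(leave-one-out refits at every elimination step of every inner fold), so
fitting goes through a compiled Newton–Raphson kernel on the Breslow
partial likelihood rather than a general-purpose survival package. Rows
are sorted once per training fold by descending time; the observed
information is accumulated as

    H = X' diag(w c) X − sum_g d_g mu_g mu_g' ,

where w_i are hazard weights exp(eta_i), c_i sums d_t/S0(t) over event
times t at or before patient i's time (a suffix-sum pass), and mu_g is the
risk-set-weighted covariate mean at event time g — one O(nk) pass plus two
small matrix products per iteration. Step halving guards ascent;
convergence is declared on a score max-norm below 1e-7 or a relative
log-likelihood gain below 1e-9, which on test problems reproduces R's
`coxph(ties="breslow")` coefficients to ~1e-11 and lifelines (tie-free
data, tightened precision) to ~1e-13. Standard errors are Wald, from the
inverse information at the optimum. |beta| > 50 on any coordinate is
treated as divergence (separation).

The test suite cross-checks this solver against two independent
implementations — scikit-survival (`ties="breslow"`) on heavily tied data
and lifelines on tie-free data. (lifelines itself applies the Efron tie
correction, so the two agree only without ties; this is why the tied-data
oracle is scikit-survival.)

## Synthetic cohorts

No individual-level data are distributed with the package; a generator
produces cohorts with the structure the analysis assumes:

* **Marker scores** (`aqua_marker`): clipped log-normal on [0, 255]
  (defaults mu = 3.0, sigma = 0.8 on the log scale — median ≈ 20,
  right-skewed, "predominantly low"), emulating fluorescence intensity
  scores without reproducing any cohort-specific histogram.
* **IHC receptor scores** (`ihc_marker`): ordinal 0–3 with positivity
  rates near a typical breast-cancer cohort (ER 52%, PR 46%, HER2 14%).
* **Clinical variables**: nodal status Bernoulli(0.5) (a half/half
  node-negative/node-positive design), tumor size log-normal solved to
  give mean 2.9 cm with 59% above 2 cm, nuclear grade 1–3 with mix
  0.20/0.52/0.28, age normal (58, 13) clipped to 24–88.
* **Outcome**: hazard(t|x) = h0(t) exp(sum beta_j x_j) with an exponential
  (default rate 0.035/yr) or Weibull baseline; event times by inverse
  cumulative-hazard sampling. Because covariates are raw-scaled, the
  cohort-mean linear predictor is absorbed into the baseline (a pure
  reparameterization that leaves every Cox coefficient unchanged) so the
  nominal baseline rate — and the ~35–40% 15-year event fraction — holds
  whatever betas are planted. Effect sizes are most naturally specified
  per SD via `betas_for_hr_per_sd`, which converts a hazard ratio per
  standard deviation into a per-unit log hazard ratio using a large
  fixed-seed reference draw.
* **Censoring**: uniform on (0, 2 × horizon], independent of covariates,
  plus administrative truncation at the 15-year horizon — mixed censoring
  as in any long-follow-up cohort, honoring the independence the ATD
  evaluation assumes.
* **Dependence**: optional Gaussian copula on ranks, preserving the
  marginal families.

What the generator does **not** emulate: measurement error or batch
effects in marker scoring, missingness (cohorts are complete-case by
construction; the reader applies the complete-case filter to real files),
covariate-dependent censoring, non-proportional hazards, or the actual
joint distribution of the clinical variables (they are independent unless
a copula is requested, whereas real size/grade/nodal status are
correlated). Passing tests therefore certify the *procedure* — metric
correctness, selection behavior, calibration — on data satisfying the
model's assumptions, not the clinical performance of any marker panel on
real patients.

## Stratified analyses

The Nottingham Prognostic Index is the standard Galea formula
`0.2 * size_cm + grade + node_stage`; binary nodal status maps to stage as
negative → 1, positive → 2 (configurable), since the index expects a
three-level stage. The cohort is binarized at the NPI midpoint 4.4, with
patients at exactly 4.4 assigned to the lower-risk group. The
node-negative / hormone-receptor-positive subpopulation keeps patients
with negative nodal status and ER and/or PR score > 0 and drops nodal
status from the modeling set (constant in the stratum), leaving 17 of 18
variables. Score distributions are compared with a two-sided Mann–Whitney
U test: exact null distribution when both samples have ≤ 20 values,
tie-corrected normal approximation otherwise (via scipy).

## Problem sizes used in the shipped checks

The published procedure runs 100 repeats of the outer loop on a
638-patient cohort. The package defaults to `n_repeats=100`, but its own
test and reproduction runs use scaled-down sizes chosen to exercise every
code path with comfortable statistical margins: selection-recovery
experiments use 20 master seeds × 10 repeats at n = 600 with four planted
signals of hazard ratio 2 per SD; the model-family comparison uses 10
repeats; null calibration uses 10 repeats at n = 400; the reproduction
script (`scripts/acceptance.py`) uses 5 repeats per analysis. At these
sizes each pooled score distribution still has 50–200 fold-level values,
ample for the Mann–Whitney comparisons performed on them.

## Known limitations

* Only right-censored, single-event (cause-specific) survival; no
  competing risks, time-varying covariates, stratified baselines, or
  penalized fitting.
* The ATD-AUCROC here is the unweighted average over death events; the
  IPCW-weighted cumulative/dynamic AUC family is related but not
  implemented, and values are not directly comparable across cohorts with
  different censoring patterns.
* Backward elimination explores only the nested path; it will not find a
  better non-nested subset, by design.
* The exact Mann–Whitney branch is limited to both samples ≤ 20; beyond
  that the tie-corrected normal approximation is used.
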