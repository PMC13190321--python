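# Methods

This note documents the models, numerical choices and limitations behind the
package; it is the reference for what the defaults mean and why they are set
where they are.

## Synthetic cohorts

`syndata.generate_cohort` draws a cohort that mimics a biobank stratum of
APOL1 high-risk adults with preserved kidney function.

**Proteome.** Subjects × proteins on the log2 relative-fluorescence scale.
Each protein has an arbitrary baseline abundance (uniform on 8–12 log2
units) and spread 0.25 log2 units — a typical plasma-assay dispersion. A
planted signal block of `n_signal` proteins is drawn from a correlation
matrix with off-diagonals uniform on `panel_corr_range` (default 0.1–0.4,
the weak within-panel correlation reported for preserved-eGFR subjects),
projected to the nearest positive-definite matrix by eigenvalue clipping.
Noise proteins are independent. The generator does not model plate effects,
assay calibrators, or heavy-tailed outliers; conclusions about robustness to
those features cannot be drawn from these simulations.

**Clinical covariates.** Marginals match the published baseline table of
the preserved-eGFR stratum: age ~ N(49.2, 15.1²) truncated to ≥18, 66.5%
female, eGFR = 60 + |N(90.6, 17²) − 60| (a folded normal keeping the
stratum's mean/SD while respecting the ≥60 entry criterion), log2 UACR ~
N(log2 17.2, 1.11²) with the SD derived from the printed IQR (11–31 mg/g),
and comorbidity flags at the printed prevalences. Creatinine is derived by
inverting the 2021 CKD-EPI equation so that the clinical table is internally
consistent.

**Outcomes.** Event times follow a Weibull proportional-hazards model
S(t|x) = exp(−(t/scale)^shape · e^lp). The linear predictor combines the
planted protein effects (`true_betas`, log hazard ratios per log2 unit;
defaults are the published score's thirteen coefficients restricted to its
nine proteins) and clinical effects on the score's conventional scales (0.19
per 10 years of age, 0.49 for male, −0.27 per 5 eGFR units, 0.22 per UACR
doubling), each centered at the cohort mean. Censoring is the minimum of
exponential dropout (`censor_rate`) and an administrative horizon (10
years). The default shape 1.2 gives mildly increasing baseline hazard;
shape/scale (1.2, 56.0) and dropout 0.045/yr were calibrated once by Monte
Carlo so that the default cohort shows ≈18% observed ten-year events and
≈7.2 years mean follow-up, matching the study stratum. Event types are
labeled kidney vs death with probability 0.66/0.34, the approximate split of
the printed event table; the label is independent of covariates, so
cause-specific analyses on synthetic data test machinery, not biology.

**eGFR trajectories** are linear per subject (baseline + slope·t + visit
noise, truncated at 1), with an optional "progressor" fraction given a steep
negative slope; this feeds the ≥40% decline rule. **Platform shift**
produces a second matrix whose overlapping columns are affine noisy copies
and whose `missing_targets` are all-missing, for cross-platform imputation
tests.

## Preprocessing

* Columns with missing fraction strictly greater than 0.15 are excluded
  (exactly 15% is retained).
* Chained-equation imputation regresses each incomplete column on all others
  (Bayesian ridge) and draws each missing entry from the 5 observed values
  with the closest predicted means (predictive mean matching; 5 sweeps, 5
  completed datasets). Training and test tables are imputed independently —
  no cross-fold information flow. Observed cells are never altered.
* The ≥40% eGFR-decline event fires at the *first* qualifying visit; no
  confirmation measurement is required (the outcome definition does not
  mention one; this is flagged as an assumption).
* The 2021 race-free CKD-EPI creatinine equation is hard-coded
  (κ = 0.7/0.9, α = −0.241/−0.302, 142 · 0.9938^age · 1.012 if female).
* Train/test splitting is stratified on the event indicator
  (`StratifiedShuffleSplit`), 80/20 by default.
* Cross-platform imputation first rescales overlapping columns to the source
  scale by median/IQR matching (rank-preserving affine), then predicts
  absent targets with a multi-output ridge regression fit only on source
  training data.

## Penalized Cox fitting

The native path solver maximizes the Breslow partial likelihood scaled by
1/n minus λ(α‖β‖₁ + (1−α)‖β‖₂²/2) on the penalized coordinates, by
glmnet-style IRLS with cyclical coordinate descent: warm starts down a
log-spaced λ path (λ_max to 10⁻³·λ_max over 100 points), sequential
strong-rule screening with a KKT pass that doubles as the next λ's screen,
and an optional early path stop when the relative likelihood gain saturates
(10⁻⁵). Covariates are centered internally (coefficient-neutral for a Cox
model, but it keeps the coordinate updates well conditioned). Unpenalized
fits (λ = 0) instead use full-Hessian Newton–Raphson with step-halving, and
report Wald standard errors from the observed information. Ties are handled
by the Breslow approximation throughout.

Two solver profiles are used deliberately: grid searches inside the ensemble
run with loose tolerance (10⁻⁴) and at most two IRLS reweights per λ —
agreement with the exactly solved path was verified (non-zero pattern
99.9%, max coefficient difference < 5·10⁻³), and the test suite also
cross-checks the path against scikit-survival's Coxnet; final refits and
anything feeding reported coefficients run at tight tolerance.

## Screening and the ensemble

The univariate screen fits one Cox model per protein (vectorized Newton),
takes Wald p-values, adjusts by Benjamini–Hochberg over all tested proteins,
keeps adjusted p < 0.05, and truncates to the best 20% of tested proteins by
p-value rank (BH first, then the truncation — the procedure's ordering is
ambiguous in prose; this reading is fixed here). Note that in a correlated
block with mixed coefficient signs a protein's marginal association can be
much weaker than its conditional effect; the screen is marginal by design.

Candidate panels sample 40–90% of the screened set uniformly without
replacement, deduplicated, with a capacity check for small sets. Each panel
is scored on a shared fold assignment (event-stratified, 8 folds) over the
full α × λ grid; the per-panel optimum is the strict maximizer of the mean
held-out C-index, with exact ties broken toward larger λ then smaller α.
The default ensemble size (300 panels) is a desk-scale working default —
selection frequencies from 150- and 450-panel ensembles on the same data
rank-correlate strongly — and can be scaled up by configuration; the
procedure in the source study used on the order of 10⁶ panels over ~1,500
screened proteins.

A protein's selection frequency divides by the number of panels *containing*
it (not all panels), correcting for unequal sampling exposure. The stable
set is frequency ≥ 0.30.

**Known limitation — stability at low dimension.** With only tens of
screened proteins, the CV-maximal per-panel optimum retains any noise
protein that happens to be associated with outcome in the one observed
dataset (|z| ≳ 2 arises several times among ~60 noise proteins at n = 600),
and such proteins recur across panels, exceeding the 0.30 threshold. The
false-positive control of the stability filter therefore depends on the
screened set being much larger than the per-panel active set, as it is at
the source study's dimensionality; at desk scale the stable set should be
read as "planted markers plus a few dataset-specific correlates". This is a
property of the procedure, reproduced identically by an independent solver,
not of the implementation.

The final refit standardizes the stable proteins (training mean/SD, stored
in the model), adds age/10, eGFR/5, log2 UACR and a male indicator
(unpenalized by default), and repeats the grid search; an optional
pre-filter can drop one of any protein pair with |R| > 0.9.

## Scoring conventions

Protein inputs to the published coefficients are taken as z-scored log2
abundances — the publication does not state the protein scale, and this is
the package's documented assumption; `ScoreModel.protein_scaling` carries
the cohort scalings, and `None` means inputs are pre-standardized. Clinical
terms are log2(UACR), age/10, eGFR/5 and a male indicator, uncentered, per
the printed formula. Quintiles are rank-based with stable tie-breaking
(sizes n/5 ± 1; a warning reports ties spanning a boundary). The quintile
gradient contrast fits both scores' per-quintile-step terms in one Cox model
and Wald-tests the slope difference; an indicator-based per-quintile fit is
exposed as a cross-check. Identical score vectors short-circuit to Δ = 0,
p = 1 (the joint model is singular there).

## Evaluation framework

IPCW weights use the marginal Kaplan–Meier estimator of the censoring
distribution (covariate-conditional censoring models are out of scope; the
marginal estimator is the standard choice). Cases at horizon t (event by t)
weigh 1/Ŝ_c(T⁻); event-free subjects beyond t weigh 1/Ŝ_c(t); subjects
censored before t are uninformative (weight 0). Weights are capped at 20
with a logged warning when Ŝ_c is tiny. AUC(t) is the IPCW-weighted
Wilcoxon statistic with cumulative cases and dynamic controls; the summary
tAUC and the per-metric means M̄ weight timepoints by the event-process KM
survival Ŝ(t). Threshold metrics use the Youden maximizer over observed
score values, ties broken toward the higher threshold (more specific rule).
AUC-type quantities and report summaries are on the 0–100% scale;
single-confusion-matrix rates are fractions.

Competing-risk incidence is Aalen–Johansen (lifelines); cause-specific
AUC keeps subjects with the competing event in the control set by default
(configurable to censor them), and the choice is recorded in the output.
Decision-curve net benefit is TP/n − (FP/n)·p/(1−p) with IPCW event status
at the horizon, against treat-all and treat-none references. The
proportional-hazards diagnostic is the Grambsch–Therneau score test on
Schoenfeld residuals (identity, rank, or KM time transforms; KM default),
validated against R's `survival::cox.zph` on fixtures and calibrated by
simulation (type-I ≈ 4–6% at α = 0.05). Sample size: Schoenfeld events
d = (z₁₋α/₂ + z₁₋β)²/(p(1−p)·ln²HR) with n = d/event rate rounded to the
nearest integer (events rounded up), plus an events-per-variable mode
(EPV × predictors); the inverse mode returns achieved power.

## Problem sizes and determinism

Unit tests run on cohorts of 300–2,000 subjects and 5–60 proteins; the
ensemble-recovery check uses ten cohorts of n = 600 with 60 proteins and 300
panels each, and the end-to-end reproduction script uses one 851 × 1,000
cohort — sizes chosen so the whole suite runs on a laptop-class single CPU.
Every stochastic step consumes an explicit seed (child seeds derived by
`SeedSequence`); identical configurations produce byte-identical artifacts,
and the pipeline manifest records config and artifact hashes.
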