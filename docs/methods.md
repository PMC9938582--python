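# Methods

## Scope and data model

The package analyses total serum *N*-glycome profiles measured by HILIC-UHPLC as 39
chromatogram peak areas (GP1–GP39) in patients with advanced melanoma starting
immune-checkpoint-inhibitor (ICI) therapy. Three inputs drive every analysis: a peak
table (one row per sample: sample id, patient id, measurement batch, days from ICI
start, 39 positive areas), a clinical table (one row per patient: age at advanced
melanoma diagnosis, sex, BMI, dichotomised LDH, ECOG performance status, metastatic
stage, BRAF status, centre, regimen, responder label, PFS/OS times and event flags),
and a declarative derived-trait definition file.

## Preprocessing

Raw areas are compositional: only relative peak abundances are meaningful. The chain
is fixed and stage-stamped:

1. **Total-area normalisation** — each row divided by its sum over the 39 peaks;
   output rows close to 1 exactly.
2. **Natural log.** The base is irrelevant downstream (linear models and ranks);
   zero fractions are not expected from chromatogram areas and raise unless a
   pseudo-fraction (half the smallest positive column value) is explicitly enabled.
3. **Batch correction** — parametric empirical-Bayes location/scale adjustment
   (ComBat), batch-only design, implemented in-package and cross-checked against
   independent reference implementations. A single batch is an identity. Note one
   inherent property: when all features share an identical batch offset, the
   feature-level prior variance collapses and per-feature sampling noise is shrunk
   toward the common offset rather than removed; with heterogeneous offsets (the
   realistic case) batch means are removed to well under 0.05 log units at n = 200
   per batch.
4. **Outlier masking** — per glycan, values more than 3 sample SDs from the column
   mean are set missing. Mean and SD are computed once on the incoming values; the
   rule is not iterated. Applied to the sample set of the analysis at hand
   (pre-treatment samples for the cross-sectional analyses).
5. **Inverse-normal transform** — rank-based, Blom offset (r − 3/8)/(n + 1/4),
   average ranks for ties, missing cells preserved. Output columns have mean 0 and
   SD ≈ 1, so Cox hazard ratios are per SD.

Derived traits are computed on the relative-abundance stage as
(sum of numerator peaks)/(sum of denominator peaks) and then pass through the same
log → batch → outlier → inverse-normal chain. The shipped 16 defaults cover low/high
branching, oligomannose, core and antennary fucosylation, bisecting GlcNAc, and
galactosylation/sialylation degrees; they are a best-effort reconstruction from the
packaged peak annotation and are fully overridable — analyses always use the
definitions actually supplied.

## Multiplicity and power

The 39 peaks (and 16 traits) are strongly correlated, so Bonferroni correction uses
the Li & Ji effective number of tests: with eigenvalues λᵢ of the variables'
correlation matrix, N_eff = Σᵢ [I(|λᵢ| ≥ 1) + (|λᵢ| − ⌊|λᵢ|⌋)], reported rounded
half-away-from-zero, thresholds α/N_eff. The correlation matrix is computed on
pre-treatment values with pairwise-complete Pearson correlation (configurable to
Spearman). Eigenvalues within numerical noise of an integer are snapped to it so the
degenerate oracles (identity → p, rank one → 1) are exact.

Two-group power at Cohen's *d* uses the exact noncentral-*t* distribution with
noncentrality d/√(1/n₁ + 1/n₂) and df = n₁ + n₂ − 2. At the study margins this gives
72.8% (n = 49/39, d = 0.8, α = 0.05/20), 84.5% (α = 0.05/6) and 70.1%
(n = 34/20, α = 0.05/2 = 0.025) — matching the conventionally truncated integer
percentages 72/84/70.

## Association testing and permutation validation

Per variable, ordinary least squares of the (inverse-normal) value on the responder
label plus covariates (sex, age, BMI, LDH, ECOG as categorical; sparse ECOG levels
merged downward when a level has fewer than 2 patients). The glycan is the response
and the label the predictor, so β is the standardised group difference after
covariate adjustment; p-values are two-sided.

Significant hits are validated by permutation. All permutation stages share the
add-one estimator eP = (T + 1)/(B + 1), which never returns 0. Two counting rules
are provided:

- `criterion="threshold"` — T counts permutations whose refit p-value beats the fixed
  Bonferroni threshold. This is the validation construction used for the confirmed
  flags (confirmation threshold 0.05/N_sig recomputed from the run's own number of
  significant hits per family).
- `criterion="observed"` — T counts permutations at least as extreme as the observed
  statistic. This is the standard permutation p-value, uniform under the null, and is
  what the calibration suite exercises; the threshold form is a property of the
  threshold, not of the observed statistic, and is not null-uniform by construction.

Label permutations shuffle the responder labels over the whole cohort with covariates
and glycans fixed; the per-permutation refit uses the Frisch–Waugh–Lovell
residualisation, which reproduces the full-model t-test exactly at a fraction of the
cost (asserted against per-permutation OLS refits in the tests).

PERMANOVA (Euclidean distances on the column-standardised complete matrix, i.e. the
batch-corrected stage before outlier masking) uses the McArdle–Anderson hat-matrix
trace partition with sequential (covariates-first) sums of squares — the adonis
convention — and free permutation of sample rows.

## Response prediction

Binomial GLMs (IRLS Newton) predict the responder label from clinical terms (age,
sex, BMI, stage, LDH, ECOG; sparse stage levels merged) with or without the
associated glycans. Performance is the Mann–Whitney AUC of the pooled leave-one-out
held-out probabilities — folds have one observation, so pooling is the only coherent
aggregate. Quasi-separation in a fold falls back to a ridge-stabilised fit
(penalty 10⁻⁴) rather than dropping the fold. The glycan contribution over the
clinical model is tested by permuting the glycan sub-matrix rows as one set
(preserving intra-subject correlation exactly — same rows, reordered) and recomputing
the full LOOCV AUC per permutation; eP = P(AUC_perm ≥ AUC_obs).

## Survival analysis

One glycan at a time enters a Cox proportional-hazards model with the clinical
covariates. Fitting maximises the Efron-tie partial likelihood by Newton–Raphson
with step-halving and a trust-region cap on the step length; a likelihood plateau
(e.g. a factor level with no events drifting to −∞) is detected via the score norm
and treated as converged, matching the behaviour of standard survival software.
Significance is a likelihood-ratio test against the covariate-only null; hazard
ratios are per SD with Wald 95% intervals. A zero-variance glycan returns HR = 1,
p = 1. Fits with fewer than 10 events (configurable floor) are refused; non-converged
fits are discarded downstream.

The Grambsch–Therneau global diagnostic regresses Schoenfeld residuals on the
centred Kaplan–Meier transform g(t) = 1 − KM(t⁻) of event time:
χ² = d · u′V̂u / Σ(g − ḡ)², u = Σ(gₖ − ḡ)sₖ, df = number of model terms (identity and
rank transforms available). Under proportional hazards its rejection rate at
α = 0.05 calibrates to [0.02, 0.09] in simulation. When the global p ≤ 0.05 the
association is re-assessed on a partitioned time axis: short term (< 180 d,
administrative censoring at 180), medium (180–360 d, left truncation at 180,
censoring at 360) and long (> 360 d, left truncation at 360). Covariate columns that
become constant within a term's risk set are dropped with a warning. Validation
permutes glycan values within quartiles of the covariate-only model's linear
predictor — preserving the empirical covariate–outcome–glycan relationship — and
refits per permutation, warm-starting Newton from the observed fit. Kaplan–Meier
curves by glycan tertiles with a 3-sample log-rank test give the graphical summary
(lifelines backs both).

## Longitudinal shifts

Follow-up samples map to windows by day offsets (1 week = 7 days): early [14, 35),
late [35, 84]; samples before day 7 or after day 84 are discarded, as are samples at
[7, 14), which fall between the printed window definitions. Within a window the
sample nearest the window median (21 d early, 63 d late) wins, ties to the earlier
sample; patients whose baseline-to-early gap exceeds 49 days leave the early
analysis. The baseline is the latest pre-treatment sample. Window assignment is a
pure function of the day offsets.

Shifts (baseline − follow-up) are tested on batch-corrected log relative abundances
— the paired Wilcoxon test is rank-based, and median differences stay interpretable
on the abundance scale — without inverse-normal transformation. The signed-rank test
uses the exact null distribution for ≤ 25 non-zero pairs (including tied magnitudes)
and the tie/continuity-corrected normal approximation otherwise. Swap permutation
exchanges each patient's pair with probability ½ (independent fair coins; a
fixed-count variant is available), recomputing the test per permutation. Significant
shifts are then regressed on the responder label with covariate adjustment at a
Bonferroni threshold of 0.05 divided by the number of shift variables tested
(0.025 when two variables are tested — the arithmetic 0.05/2; see the design notes).

## Synthetic cohort generator

The generator defines the study conditions; its defaults mirror the cohort the
analyses were designed for: 88 patients, exactly 49 responders / 39 non-responders by
quota sampling; age ~ N(60.5, 15.0) years, 64.8% male, BMI ~ N(28.0, 5.4),
34.1% LDH-high, ECOG 0–3 at (53.4, 35.2, 9.1, 2.3)%, stage and regimen at the printed
frequencies; three centres at 14/40/34.

Latent log peak levels are multivariate normal with a block-diagonal correlation
(default 8 structural-family blocks, within-block r = 0.45, per-peak SD 0.25 log
units) around a fixed baseline profile with a few dominant peaks, as in real
chromatograms. Raw areas are exp(latent + batch offset) times an arbitrary
per-injection intensity, so normalisation is genuinely downstream's job. Batch
offsets are N(0, 0.25) per batch × peak across 3 batches.

Planted effects: response effects add d·SD to responders' latent means
(label-conditional, so the planted Cohen's d is exact by construction);
survival follows exponential proportional hazards with linear predictor
log(HR)·z_peak plus moderate covariate effects (age, LDH, ECOG), independent
exponential censoring calibrated to the requested rate plus administrative censoring
at day 900; a piecewise variant switches the glycan log-hazard at a cut day for
time-partition recovery tests. Baseline PFS/OS hazards (1/170 and 1/270 per day)
give mean PFS ≈ 5–6 months and OS ≈ 9 months; OS is floored at PFS. Follow-up visits
(75% of patients; early ~ N(21, 4) d, late ~ N(43, 12) d; baselines mostly within a
month before start with a tail to 4 months) add within-subject noise (SD 0.10) and
the planted on-treatment log shifts.

What the generator does **not** emulate: chromatogram integration error structure,
heavy-tailed or skewed abundance distributions, informative censoring, visit
scheduling tied to progression, missing covariates, and any real correlation between
clinical covariates and the glycome. Passing tests therefore demonstrate statistical
correctness and calibration of the machinery under the stated generative model, not
biological validity on real cohorts.

Two compositional facts surface in tests and are worth knowing: closure induces a
weak negative background correlation (~0.08) among all log relative abundances even
when latent peaks are independent, and a planted shift on a dominant peak spills
into every other relative abundance.

## Numerical choices

- Efron tie handling throughout; partial-likelihood evaluation is vectorised over
  event times via precomputed risk-set masks (tied event times fall back to the
  per-tie adjustment).
- Newton convergence: likelihood gain < 10⁻⁹ with small step, or score norm < 10⁻⁷
  (plateau); step length capped at 5 per iteration; |β| > 50 flags monotone
  likelihood as non-convergence.
- Inverse-normal offset: Blom. Outlier SD: sample (ddof = 1).
- ComBat iteration tolerance 10⁻⁴ (the reference convention); hyperprior variance
  uses ddof = 1.
- Per-stage seeds derive from the master seed and the stage name (CRC32 mix), so
  toggling stages never perturbs other stages' randomness; all seeds stay below 2³¹.
- LOOCV ridge fallback 10⁻⁴; logistic separation detected by runaway coefficients
  (|β| > 15) at numerical convergence.

## Known limitations

- The peak annotation and default trait definitions are a reconstruction; real
  deployments should supply their laboratory's own definitions.
- Time-partitioned analyses condition on survival to the interval start (left
  truncation) rather than re-zeroing clocks; the alternative is noted in the code.
- PERMANOVA requires a complete matrix and so runs before outlier masking.
- The permutation validation in threshold mode inherits the discreteness of
  (T+1)/(B+1); at reduced permutation counts the confirmation thresholds can be
  unattainable (1/(B+1) above 0.05/N_sig), which matters for smoke runs, not for the
  default B = 5000.
- Simulation sizes in the test suite (200 replicate cohorts at 99 permutations for
  calibration; n = 500–800 for recovery) balance statistical resolution against a
  single-CPU run of a few minutes.
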