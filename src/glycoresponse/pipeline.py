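"""End-to-end orchestration: simulate/load -> preprocess -> traits ->
multiplicity -> associations -> prediction -> survival -> longitudinal.

Each stage writes a TSV plus a JSON sidecar with the parameters, derived
seed and in/out counts; a single run log records every discard decision.
Per-stage seeds derive from the master seed and the stage name so toggling
one stage never perturbs another's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, longitudinal, multiplicity, prediction, simulate, survival
from .preprocess import (
    NormalizedGlycome,
    preprocess_chain,
    total_area_normalize,
    transform_values_like_peaks,
    write_processed,
)
from .traits import compute_traits, default_trait_specs, load_trait_spec

ALL_STAGES = ("preprocess", "traits", "multiplicity", "orr", "prediction", "survival", "longitudinal")


@dataclass
class RunConfig:
    peaks_path: str | None = None
    clinical_path: str | None = None
    trait_spec_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    alpha: float = 0.05
    n_perm_label: int = 5000
    n_perm_block: int = 1000
    n_perm_quartile: int = 5000
    n_perm_swap: int = 1000
    n_perm_permanova: int = 999
    seed: int = 0
    outdir: str = "run"
    stages: tuple = ALL_STAGES
    min_events: int = 10

    def validate(self) -> None:
        has_paths = self.peaks_path is not None and self.clinical_path is not None
        if has_paths == (self.simulation is not None):
            raise ValueError("provide exactly one of input paths or a simulation block")
        for name in ("n_perm_label", "n_perm_block", "n_perm_quartile", "n_perm_swap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig(
                **{k: (tuple(v) if k == "block_sizes" else v) for k, v in sim.items()}
            )
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic child seed: crc32 of the stage name mixed with the master."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def validate_inputs(peaks: pd.DataFrame, clinical: pd.DataFrame) -> list:
    """Referential-integrity and sanity report (list of severity/message dicts)."""
    report = []

    def add(severity, message):
        report.append({"severity": severity, "message": message})

    known = set(clinical["patient_id"])
    for pid in peaks["patient_id"].unique():
        if pid not in known:
            add("error", f"peak rows reference unknown patient {pid}")
    with_peaks = set(peaks["patient_id"])
    for pid in known - with_peaks:
        add("warning", f"clinical row for {pid} has no peak rows")
    peak_cols = [c for c in peaks.columns if c.startswith("GP")]
    n_bad = int((peaks[peak_cols] <= 0).any(axis=1).sum())
    if n_bad:
        add("error", f"{n_bad} sample rows with non-positive peak areas")
    base = peaks[peaks["days_from_ici_start"] <= 0]
    for pid, grp in base.groupby("patient_id"):
        if len(grp) > 1:
            add("warning", f"patient {pid} has {len(grp)} pre-treatment samples")
        if (grp["days_from_ici_start"] < -122).any():
            add("warning", f"patient {pid} baseline earlier than four months before ICI start")
    for pid in with_peaks:
        if (peaks.loc[peaks["patient_id"] == pid, "days_from_ici_start"] > 0).all():
            add("warning", f"patient {pid} has no pre-treatment sample")
    dup = peaks.duplicated(subset=["patient_id", "days_from_ici_start"], keep=False)
    if dup.any():
        add("warning", f"{int(dup.sum())} duplicated visits (same patient and day)")
    for col in ["age", "sex", "bmi", "ldh_high", "ecog", "orr"]:
        if col in clinical and clinical[col].isna().any():
            add("warning", f"missing values in clinical column {col}")
    return report


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines = []

    def log(self, msg: str):
        self.lines.append(msg)

    def flush(self):
        self.path.write_text("\n".join(self.lines) + "\n")


def _sidecar(outdir: Path, stage: str, payload: dict):
    with open(outdir / f"{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in fixed order; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")

    if config.simulation is not None:
        cohort = simulate.simulate_cohort(config.simulation, seed=stage_seed(config.seed, "simulate"))
        simulate.write_cohort(cohort, outdir / "input")
        peaks, clinical = cohort.peaks, cohort.clinical
        log.log(f"simulated cohort: {len(clinical)} patients, {len(peaks)} samples")
    else:
        peaks = pd.read_csv(config.peaks_path, sep="\t")
        clinical = pd.read_csv(config.clinical_path, sep="\t")
        log.log(f"loaded {len(clinical)} patients, {len(peaks)} samples")

    report = validate_inputs(peaks, clinical)
    for entry in report:
        log.log(f"[{entry['severity']}] {entry['message']}")
    if any(e["severity"] == "error" for e in report):
        log.flush()
        raise ValueError("input validation failed; see run.log")

    clinical = clinical.set_index("patient_id", drop=False)
    results: dict = {}

    # ---- preprocessing (pre-treatment samples feed the cross-sectional stages)
    pre_rows = peaks[peaks["days_from_ici_start"] <= 0]
    pre_rows = pre_rows.sort_values("days_from_ici_start").groupby("patient_id").tail(1)
    if "preprocess" in config.stages:
        g_pre = preprocess_chain(pre_rows)
        write_processed(g_pre, outdir / "peaks_pretreatment_inverse_normal.tsv")
        _sidecar(outdir, "preprocess", {"n_samples": len(g_pre.values), "stage": g_pre.stage,
                                        "outliers_removed": g_pre.removed})
        log.log(f"preprocess: {len(g_pre.values)} pre-treatment samples")
    else:
        return _finish(outdir, log)
    by_patient = g_pre.meta["patient_id"]
    peak_values = g_pre.values.set_axis(by_patient.loc[g_pre.values.index], axis=0)

    # ---- derived traits
    trait_values = None
    if "traits" in config.stages:
        specs = (
            load_trait_spec(config.trait_spec_path)
            if config.trait_spec_path
            else default_trait_specs()
        )
        rel = total_area_normalize(pre_rows)
        traits_rel = compute_traits(rel, specs)
        g_traits = transform_values_like_peaks(traits_rel, rel.meta)
        trait_values = g_traits.values.set_axis(
            g_traits.meta.loc[g_traits.values.index, "patient_id"], axis=0
        )
        trait_values.to_csv(outdir / "traits_pretreatment_inverse_normal.tsv", sep="\t")
        _sidecar(outdir, "traits", {"n_traits": trait_values.shape[1]})
        log.log(f"traits: {trait_values.shape[1]} derived traits")

    # ---- multiplicity
    rel_pre = total_area_normalize(pre_rows)
    neff_m = multiplicity.li_ji_neff(
        multiplicity.correlation_for_neff(rel_pre.values), alpha=config.alpha
    )
    results["neff_measured"] = neff_m
    log.log(f"multiplicity: N_eff measured = {neff_m.n_eff_reported} "
            f"(raw {neff_m.n_eff_raw:.2f}), threshold {neff_m.threshold:.3e}")
    neff_d = None
    if trait_values is not None:
        specs_rel = compute_traits(rel_pre, default_trait_specs() if config.trait_spec_path is None
                                   else load_trait_spec(config.trait_spec_path))
        neff_d = multiplicity.li_ji_neff(
            multiplicity.correlation_for_neff(specs_rel), alpha=config.alpha
        )
        results["neff_derived"] = neff_d
        log.log(f"multiplicity: N_eff derived = {neff_d.n_eff_reported}, "
                f"threshold {neff_d.threshold:.3e}")
    if "multiplicity" in config.stages:
        power = multiplicity.two_sample_power(
            int(clinical["orr"].sum()),
            int((1 - clinical["orr"]).sum()),
            0.8,
            neff_m.threshold,
        )
        _sidecar(outdir, "multiplicity", {
            "neff_measured_raw": neff_m.n_eff_raw,
            "neff_measured": neff_m.n_eff_reported,
            "threshold_measured": neff_m.threshold,
            "neff_derived": None if neff_d is None else neff_d.n_eff_reported,
            "threshold_derived": None if neff_d is None else neff_d.threshold,
            "power_large_effect_measured": power,
        })

    orr = clinical["orr"]
    covariates = clinical[["age", "sex", "bmi", "ldh_high", "ecog", "stage"]]

    # ---- ORR association + label-permutation validation
    if "orr" in config.stages:
        seed = stage_seed(config.seed, "orr")
        # multivariate stratification check on the scaled complete matrix
        g_bc = preprocess_chain(pre_rows, stop_after="batch_corrected")
        bc_values = g_bc.values.set_axis(g_bc.meta.loc[g_bc.values.index, "patient_id"], axis=0)
        permanova_rows = []
        for factor in ("centre", "regimen", "braf", "stage", "ldh_high", "ecog"):
            if factor not in clinical:
                continue
            try:
                pr = association.permanova(
                    bc_values,
                    clinical[factor],
                    covariates=clinical[["sex", "age"]],
                    n_perm=config.n_perm_permanova,
                    seed=stage_seed(config.seed, f"permanova:{factor}"),
                )
            except ValueError as exc:
                log.log(f"permanova[{factor}]: {exc}; skipped")
                continue
            permanova_rows.append({"factor": factor, **{k: pr[k] for k in ("pseudo_F", "p")}})
            log.log(f"permanova[{factor}]: F = {pr['pseudo_F']:.2f}, p = {pr['p']:.3f}")
        if permanova_rows:
            pd.DataFrame(permanova_rows).to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        families = {"measured": (peak_values, neff_m.threshold)}
        if trait_values is not None and neff_d is not None:
            families["derived"] = (trait_values, neff_d.threshold)
        frames = []
        for family, (vals, thr) in families.items():
            res = association.associate_orr(vals, orr, covariates, thr)
            res["family"] = family
            n_sig = int(res["significant"].sum())
            res["eP"] = np.nan
            res["confirmed"] = False
            if n_sig:
                eps = association.label_permutation_validate(
                    vals, orr, covariates, thr,
                    n_perm=config.n_perm_label, seed=seed,
                    variables=res.index[res["significant"]].tolist(),
                )
                conf_thr = config.alpha / n_sig
                for var in eps.index:
                    res.loc[var, "eP"] = eps.loc[var, "eP"]
                    res.loc[var, "confirmed"] = eps.loc[var, "eP"] < conf_thr
                log.log(f"orr[{family}]: {n_sig} significant, "
                        f"confirmation threshold {conf_thr:.3e}")
            frames.append(res)
        orr_results = pd.concat(frames)
        orr_results.to_csv(outdir / "orr_association.tsv", sep="\t")
        _sidecar(outdir, "orr", {"n_significant": int(orr_results["significant"].sum()),
                                 "n_perm": config.n_perm_label, "seed": seed})
        results["orr"] = orr_results

    # ---- response prediction
    if "prediction" in config.stages and "orr" in config.stages:
        seed = stage_seed(config.seed, "prediction")
        rows = []
        data = pd.concat([covariates, orr, peak_values, trait_values], axis=1)
        sig_m = orr_results[(orr_results["family"] == "measured") & orr_results["significant"]].index.tolist()
        sig_d = (
            orr_results[(orr_results["family"] == "derived") & orr_results["significant"]].index.tolist()
            if trait_values is not None else []
        )
        specs = [prediction.PredictionModelSpec("clinical")]
        if sig_m:
            specs.append(prediction.PredictionModelSpec("clinical+measured", tuple(sig_m)))
        if sig_d:
            specs.append(prediction.PredictionModelSpec("clinical+derived", tuple(sig_d)))
        for spec in specs:
            res = prediction.loocv_auc(spec, data)
            row = {"model": spec.name, "auc": res.auc, "n": res.n, "eP_contribution": np.nan}
            if spec.glycan_terms:
                contrib = prediction.block_permutation_contribution(
                    spec, data, n_perm=config.n_perm_block, seed=seed
                )
                row["eP_contribution"] = contrib["eP"]
            rows.append(row)
            res.predictions.to_csv(outdir / f"prediction_{spec.name.replace('+','_')}_oof.tsv",
                                   sep="\t", header=["p_response"])
        pred_results = pd.DataFrame(rows).set_index("model")
        pred_results.to_csv(outdir / "prediction_auc.tsv", sep="\t")
        _sidecar(outdir, "prediction", {"n_perm": config.n_perm_block, "seed": seed})
        results["prediction"] = pred_results
        for _, r in pred_results.iterrows():
            log.log(f"prediction[{r.name}]: AUC = {r['auc']:.3f}")

    # ---- survival
    if "survival" in config.stages:
        seed = stage_seed(config.seed, "survival")
        sur_covariates = clinical[["age", "sex", "bmi", "ldh_high", "ecog"]]
        frames = []
        for endpoint in ("pfs", "os"):
            outcome = pd.DataFrame(
                {"time": clinical[f"{endpoint}_days"], "event": clinical[f"{endpoint}_event"]}
            )
            for family, vals in [("measured", peak_values)] + (
                [("derived", trait_values)] if trait_values is not None else []
            ):
                thr = (neff_m if family == "measured" else neff_d).threshold
                for var in vals.columns:
                    try:
                        fit = survival.cox_fit(vals[var], outcome, sur_covariates,
                                               min_events=config.min_events)
                    except ValueError as exc:
                        log.log(f"survival[{endpoint}/{var}]: {exc}; skipped")
                        continue
                    if not fit.converged:
                        log.log(f"survival[{endpoint}/{var}]: non-convergence; discarded")
                        continue
                    fits = [fit]
                    if survival.ph_test(fit) <= 0.05:
                        log.log(f"survival[{endpoint}/{var}]: PH violated; time-partitioned")
                        fits = survival.time_partitioned_cox(vals[var], outcome, sur_covariates)
                    for f in fits:
                        f.significant = bool(f.converged and f.p_lrt < thr)
                        frames.append({
                            "endpoint": endpoint, "family": family, "variable": var,
                            "term": f.term, "hr": f.hr, "ci_low": f.ci_low,
                            "ci_high": f.ci_high, "p_lrt": f.p_lrt,
                            "ph_global_p": f.ph_global_p, "n_events": f.n_events,
                            "significant": f.significant, "converged": f.converged,
                            "eP": np.nan, "confirmed": False,
                        })
        sur_results = pd.DataFrame(frames)
        if len(sur_results):
            for endpoint in ("pfs", "os"):
                outcome = pd.DataFrame(
                    {"time": clinical[f"{endpoint}_days"], "event": clinical[f"{endpoint}_event"]}
                )
                for family in sur_results["family"].unique():
                    mask = (
                        (sur_results["endpoint"] == endpoint)
                        & (sur_results["family"] == family)
                        & sur_results["significant"]
                    )
                    n_sig = int(sur_results.loc[mask, "variable"].nunique())
                    if not n_sig:
                        continue
                    thr = (neff_m if family == "measured" else neff_d).threshold
                    conf_thr = config.alpha / n_sig
                    vals = peak_values if family == "measured" else trait_values
                    for idx in sur_results.index[mask]:
                        var = sur_results.at[idx, "variable"]
                        term = sur_results.at[idx, "term"]
                        out_term = (
                            outcome if term == "full"
                            else survival._term_dataset(outcome)[term]
                        )
                        perm = survival.quartile_stratified_permutation(
                            vals[var], out_term, sur_covariates, thr,
                            n_perm=config.n_perm_quartile, seed=seed,
                        )
                        sur_results.at[idx, "eP"] = perm["eP"]
                        sur_results.at[idx, "confirmed"] = perm["eP"] < conf_thr
        sur_results.to_csv(outdir / "survival_association.tsv", sep="\t", index=False)
        _sidecar(outdir, "survival", {"n_perm": config.n_perm_quartile, "seed": seed,
                                      "min_events": config.min_events})
        results["survival"] = sur_results

    # ---- longitudinal shift
    if "longitudinal" in config.stages:
        seed = stage_seed(config.seed, "longitudinal")
        assignments = longitudinal.assign_windows(peaks)
        assignments.to_csv(outdir / "visit_windows.tsv", sep="\t", index=False)
        for _, r in assignments[assignments["window"] == "discarded"].iterrows():
            log.log(f"longitudinal discard[{r['patient_id']}/{r['sample_id']}]: "
                    f"{r['reason_discarded']}")
        keep = assignments.loc[assignments["window"] != "discarded", "sample_id"]
        rows_kept = peaks[peaks["sample_id"].isin(keep)]
        g_all = preprocess_chain(rows_kept, stop_after="batch_corrected")
        shift_frames = []
        for window in ("early", "late"):
            base, follow = longitudinal.build_pairs(g_all.values, assignments, window)
            if len(base) < 6:
                log.log(f"longitudinal[{window}]: fewer than 6 pairs; skipped")
                continue
            thr = neff_m.threshold
            res = longitudinal.paired_shift_test(base, follow, threshold=thr)
            res["window"] = window
            res["eP"] = np.nan
            sig = res.index[res["significant"].fillna(False)].tolist()
            if sig:
                eps = longitudinal.swap_permutation_validate(
                    base, follow, thr, n_perm=config.n_perm_swap, seed=seed, variables=sig
                )
                for var in eps.index:
                    res.loc[var, "eP"] = eps.loc[var, "eP"]
            shift_frames.append(res)
            if window == "early" and sig:
                shifts = (base[sig] - follow[sig])
                sv = longitudinal.shift_vs_orr(shifts, orr, covariates, alpha=config.alpha)
                sv.to_csv(outdir / "shift_vs_orr.tsv", sep="\t")
                results["shift_vs_orr"] = sv
        if shift_frames:
            shift_results = pd.concat(shift_frames)
            shift_results.to_csv(outdir / "longitudinal_shift.tsv", sep="\t")
            results["longitudinal"] = shift_results
        _sidecar(outdir, "longitudinal", {"n_perm": config.n_perm_swap, "seed": seed})

    return _finish(outdir, log)


def _finish(outdir: Path, log: _RunLog) -> Path:
    log.flush()
    return outdir
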