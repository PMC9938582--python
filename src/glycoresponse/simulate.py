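"""Synthetic ICI-glycomics cohort generator.

Emulates the statistical structure of a serum N-glycomics study in advanced
melanoma patients receiving immune checkpoint inhibitors: compositional UHPLC
peak areas with block correlation among structurally related peaks,
measurement-batch effects, clinical covariates matched to the cohort's printed
moments, a binary treatment-response label, proportional-hazards survival with
independent censoring, and follow-up visits carrying planted on-treatment
shifts.  Every planted effect is recorded in a truth object so downstream
stages can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PEAKS = [f"GP{i}" for i in range(1, 40)]

#: default partition of the 39 peaks into correlated blocks (structural families)
DEFAULT_BLOCK_SIZES = (4, 5, 5, 5, 5, 5, 5, 5)

#: baseline mean log relative share per peak; a handful of dominant peaks
#: (biantennary digalactosylated, disialylated) and a long tail of minor ones,
#: as in real total-serum chromatograms
_BASE_PROFILE_SEED = 20230218


def _baseline_log_means(n_peaks: int) -> np.ndarray:
    rng = np.random.default_rng(_BASE_PROFILE_SEED)
    raw = rng.normal(0.0, 1.1, size=n_peaks)
    raw[::7] += 1.5  # a few dominant peaks
    return raw


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 88 patients (49 responders, 39
    non-responders), 39 chromatogram peaks, covariate moments matching the
    cohort table (age 60.5 +/- 15.0 y, 65% male, BMI 28.0 +/- 5.4, 66% LDH
    normal, ECOG 0-3), exponential survival with scales giving mean PFS around
    5-6 months and OS around 9 months, and follow-up sampling for ~75% of
    patients at early (~21 d) and late (~43 d) windows.
    """

    n_patients: int = 88
    prop_responders: float = 49 / 88
    n_peaks: int = 39
    n_batches: int = 3
    batch_shift_sd: float = 0.25
    block_sizes: tuple = DEFAULT_BLOCK_SIZES
    within_block_corr: float = 0.45
    peak_sd: float = 0.25
    planted_orr_effects: dict = field(default_factory=dict)  # peak -> Cohen's d
    planted_hr_effects: dict = field(default_factory=dict)  # peak -> HR per SD
    piecewise_hr: dict = field(default_factory=dict)  # peak -> (hr_before, hr_after, cut_day)
    covariate_hr: dict = field(
        default_factory=lambda: {"age_per_decade": 1.25, "ldh_high": 1.8, "ecog": 1.35}
    )
    baseline_hazard_pfs: float = 1.0 / 170.0  # events per day
    baseline_hazard_os: float = 1.0 / 270.0
    censor_rate: float = 0.25
    admin_censor_day: int = 900
    followup_fraction: float = 66 / 88
    early_visit_fraction: float = 54 / 66
    late_visit_fraction: float = 36 / 66
    visit_noise_sd: float = 0.10
    planted_shift_effects: dict = field(default_factory=dict)  # peak -> log shift (early)
    late_shift_factor: float = 0.0
    quota_responders: bool = True
    min_events: int = 1

    def validate(self) -> None:
        if not 0 < self.prop_responders < 1:
            raise ValueError("prop_responders must lie in (0, 1)")
        if sum(self.block_sizes) != self.n_peaks:
            raise ValueError(
                f"block sizes {self.block_sizes} must partition the {self.n_peaks} peaks"
            )
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must lie in [0, 1)")
        for k, v in self.planted_hr_effects.items():
            if v <= 0:
                raise ValueError(f"hazard ratio for {k} must be > 0 (got {v})")
        corr = self.correlation_matrix()
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("implied peak correlation matrix is not positive definite")

    def correlation_matrix(self) -> np.ndarray:
        corr = np.eye(self.n_peaks)
        start = 0
        for size in self.block_sizes:
            corr[start : start + size, start : start + size] = self.within_block_corr
            start += size
        np.fill_diagonal(corr, 1.0)
        return corr

    @property
    def peak_names(self) -> list:
        return [f"GP{i}" for i in range(1, self.n_peaks + 1)]


@dataclass
class SyntheticCohort:
    peaks: pd.DataFrame  # sample_id, patient_id, batch, days_from_ici_start, GP1..GPn
    clinical: pd.DataFrame  # one row per patient
    truth: dict


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.normal(60.5, 15.0, n).clip(25, 94)
    sex = (rng.random(n) < 0.648).astype(int)  # 1 = male
    bmi = rng.normal(28.0, 5.4, n).clip(16, 50)
    ldh_high = (rng.random(n) < 0.341).astype(int)
    ecog = rng.choice(4, size=n, p=[0.534, 0.352, 0.091, 0.023])
    stage = rng.choice(
        ["III_unresectable", "M1a", "M1b", "M1c", "M1d"],
        size=n,
        p=np.array([2, 14, 17, 32, 23]) / 88.0,
    )
    braf = (rng.random(n) < 0.455).astype(int)
    centre = rng.choice(["Leeds", "PRIMM-NL", "PRIMM-UK"], size=n, p=np.array([14, 40, 34]) / 88.0)
    regimen = rng.choice(
        ["ipilimumab", "pembrolizumab", "nivolumab", "ipi+nivo"],
        size=n,
        p=np.array([1, 20, 30, 37]) / 88.0,
    )
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "age": np.round(age, 1),
            "sex": sex,
            "bmi": np.round(bmi, 1),
            "ldh_high": ldh_high,
            "ecog": ecog,
            "stage": stage,
            "braf": braf,
            "centre": centre,
            "regimen": regimen,
        }
    )


def _response_labels(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    n = cfg.n_patients
    if cfg.quota_responders:
        n_resp = int(round(n * cfg.prop_responders))
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=n_resp, replace=False)] = 1
        return labels
    return (rng.random(n) < cfg.prop_responders).astype(int)


def _survival_times(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    eta: np.ndarray,
    baseline_hazard: float,
    piecewise: list,
    z: pd.DataFrame,
) -> tuple:
    """Inverse-CDF sampling from a (piecewise-)exponential PH model."""
    n = len(eta)
    u = rng.random(n)
    target = -np.log(u)
    if not piecewise:
        t = target / (baseline_hazard * np.exp(eta))
    else:
        eta_extra_before = np.zeros(n)
        eta_extra_after = np.zeros(n)
        cut = piecewise[0][3]
        for peak, hr_before, hr_after, cut_day in piecewise:
            if cut_day != cut:
                raise ValueError("all piecewise effects must share one cut day")
            zz = z[peak].to_numpy()
            eta_extra_before += np.log(hr_before) * zz
            eta_extra_after += np.log(hr_after) * zz
        h_before = baseline_hazard * np.exp(eta + eta_extra_before)
        h_after = baseline_hazard * np.exp(eta + eta_extra_after)
        cum_at_cut = h_before * cut
        t = np.where(
            target < cum_at_cut,
            target / h_before,
            cut + (target - cum_at_cut) / h_after,
        )
    # independent exponential censoring calibrated to the requested rate,
    # plus administrative censoring at end of follow-up
    if cfg.censor_rate > 0:
        c_rate = baseline_hazard * cfg.censor_rate / (1 - cfg.censor_rate)
        c = rng.exponential(1.0 / c_rate, n)
    else:
        c = np.full(n, np.inf)
    c = np.minimum(c, cfg.admin_censor_day)
    event = (t <= c).astype(int)
    time = np.minimum(t, c)
    return np.maximum(time, 0.5).round(1), event


def simulate_cohort(config: SimulationConfig, seed: int | None = 0) -> SyntheticCohort:
    """Generate a cohort with the configured planted effects.

    Peak areas are drawn as exp(multivariate normal) with block correlation,
    batch offsets and label-conditional planted shifts; survival follows a
    proportional-hazards model on the standardized latent peak values;
    follow-up samples carry planted on-treatment log-shifts.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_patients
    peaks = config.peak_names

    clinical = _draw_covariates(rng, n)
    orr = _response_labels(rng, config)
    clinical["orr"] = orr

    # latent log peak levels: block-correlated multivariate normal
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr)
    base_mu = _baseline_log_means(config.n_peaks)
    latent = base_mu + config.peak_sd * (rng.standard_normal((n, config.n_peaks)) @ chol.T)
    latent = pd.DataFrame(latent, columns=peaks)

    # plant response effects: mean difference of d * SD on the latent log scale
    for peak, d in config.planted_orr_effects.items():
        latent[peak] += d * config.peak_sd * (orr - orr.mean())

    # standardized latent values drive survival
    z = (latent - latent.mean()) / latent.std(ddof=0)

    cov_hr = config.covariate_hr
    eta_cov = (
        np.log(cov_hr.get("age_per_decade", 1.0)) * (clinical["age"] - 60.5) / 10.0
        + np.log(cov_hr.get("ldh_high", 1.0)) * clinical["ldh_high"]
        + np.log(cov_hr.get("ecog", 1.0)) * clinical["ecog"].clip(upper=2)
    ).to_numpy()
    eta_glycan = np.zeros(n)
    for peak, hr in config.planted_hr_effects.items():
        eta_glycan += np.log(hr) * z[peak].to_numpy()
    piecewise = [(p, a, b, c) for p, (a, b, c) in config.piecewise_hr.items()]

    pfs, pfs_event = _survival_times(
        rng, config, eta_cov + eta_glycan, config.baseline_hazard_pfs, piecewise, z
    )
    os_t, os_event = _survival_times(
        rng, config, eta_cov + eta_glycan, config.baseline_hazard_os, piecewise, z
    )
    # overall survival cannot precede progression-free survival
    os_event = np.where(os_t < pfs, pfs_event | os_event, os_event)
    os_t = np.maximum(os_t, pfs)
    clinical["pfs_days"], clinical["pfs_event"] = pfs, pfs_event
    clinical["os_days"], clinical["os_event"] = os_t, os_event

    # assemble samples: baseline for everyone, follow-up visits for a subset
    rows = []
    meta = []
    batch_ids = [f"B{b+1}" for b in range(config.n_batches)]
    gamma_batch = rng.normal(0.0, config.batch_shift_sd, (config.n_batches, config.n_peaks))

    has_followup = rng.random(n) < config.followup_fraction
    for i in range(n):
        pid = clinical.at[i, "patient_id"]
        # most baselines sit close to treatment start (tail up to 4 months)
        visits = [("baseline", -min(int(rng.exponential(12.0)), 120))]
        if has_followup[i]:
            early = rng.random() < config.early_visit_fraction
            late = rng.random() < config.late_visit_fraction
            if not early and not late:
                early = True
            if early:
                visits.append(("early", int(np.clip(round(rng.normal(21, 4)), 14, 34))))
            if late:
                visits.append(("late", int(np.clip(round(rng.normal(43, 12)), 35, 83))))
        for kind, day in visits:
            b = int(rng.integers(config.n_batches))
            vals = latent.iloc[i].to_numpy().copy()
            if kind != "baseline":
                vals = vals + rng.normal(0.0, config.visit_noise_sd, config.n_peaks)
                factor = 1.0 if kind == "early" else config.late_shift_factor
                for peak, shift in config.planted_shift_effects.items():
                    vals[peaks.index(peak)] += factor * shift
            vals = vals + gamma_batch[b]
            # arbitrary overall chromatogram intensity per injection
            scale = np.exp(rng.normal(10.0, 0.3))
            rows.append(np.exp(vals) * scale)
            meta.append((f"{pid}_{kind}", pid, batch_ids[b], day))

    peak_table = pd.DataFrame(rows, columns=peaks)
    meta_table = pd.DataFrame(
        meta, columns=["sample_id", "patient_id", "batch", "days_from_ici_start"]
    )
    peaks_df = pd.concat([meta_table, peak_table.round(2)], axis=1)

    truth = {
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "planted_orr_effects": dict(config.planted_orr_effects),
        "planted_hr_effects": dict(config.planted_hr_effects),
        "piecewise_hr": {k: list(v) for k, v in config.piecewise_hr.items()},
        "planted_shift_effects": dict(config.planted_shift_effects),
        "n_responders": int(orr.sum()),
        "n_non_responders": int(n - orr.sum()),
    }
    return SyntheticCohort(peaks=peaks_df, clinical=clinical, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write peaks.tsv, clinical.tsv and truth.json; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": directory / "peaks.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.json",
    }
    cohort.peaks.to_csv(paths["peaks"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=float)
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    peaks = pd.read_csv(directory / "peaks.tsv", sep="\t")
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(peaks=peaks, clinical=clinical, truth=truth)
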