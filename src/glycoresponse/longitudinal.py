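"""On-treatment glycome shift analysis.

Follow-up samples are binned into an early (2-5 weeks) and a late (5-12
weeks) treatment window; visits within one week of treatment start or after
12 weeks are discarded, multiple candidates in a window resolve to the one
nearest the window median (3 and 9 weeks respectively, ties to the earlier
sample), and a patient whose baseline and early follow-up are more than 7
weeks apart leaves the early analysis.  Pre- vs on-treatment differences are
tested with a paired two-sided Wilcoxon signed-rank test, validated by a
swap permutation (each patient's pair exchanged with probability 1/2), and
significant shifts are tested against response with a covariate-adjusted
linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import build_covariate_matrix, _ols_single
from .multiplicity import empirical_p

EARLY = (14, 35)  # [14, 35) days = 2-5 weeks
LATE = (35, 85)  # [35, 84] days = 5-12 weeks
EARLY_MEDIAN = 21.0  # 3 weeks
LATE_MEDIAN = 63.0  # 9 weeks
MAX_BASELINE_GAP = 49.0  # 7 weeks


@dataclass
class VisitAssignment:
    patient_id: str
    window: str  # early | late | baseline | discarded
    sample_id: str | None
    days_from_start: float | None
    reason_discarded: str = ""


def _pick(candidates: pd.DataFrame, median: float) -> pd.Series:
    dist = (candidates["days_from_ici_start"] - median).abs()
    best = dist.min()
    tied = candidates[dist == best]
    return tied.sort_values("days_from_ici_start").iloc[0]


def assign_windows(samples: pd.DataFrame) -> pd.DataFrame:
    """Assign each patient's samples to baseline / early / late windows.

    ``samples`` needs columns sample_id, patient_id, days_from_ici_start.
    Returns an audit table with one row per sample, its window, and a reason
    for every discard.  Pure function of the day offsets: input order never
    matters.
    """
    rows = []
    for pid, grp in samples.sort_values(["patient_id", "days_from_ici_start"]).groupby(
        "patient_id", sort=True
    ):
        base = grp[grp["days_from_ici_start"] <= 0]
        if base.empty:
            for _, r in grp.iterrows():
                rows.append((pid, "discarded", r["sample_id"], r["days_from_ici_start"], "no baseline sample"))
            continue
        baseline = base.iloc[-1]  # latest pre-treatment sample
        for _, r in base.iterrows():
            if r["sample_id"] == baseline["sample_id"]:
                rows.append((pid, "baseline", r["sample_id"], r["days_from_ici_start"], ""))
            else:
                rows.append((pid, "discarded", r["sample_id"], r["days_from_ici_start"], "superseded baseline"))
        post = grp[grp["days_from_ici_start"] > 0]
        early_cand = post[
            (post["days_from_ici_start"] >= EARLY[0]) & (post["days_from_ici_start"] < EARLY[1])
        ]
        late_cand = post[
            (post["days_from_ici_start"] >= LATE[0]) & (post["days_from_ici_start"] < LATE[1])
        ]
        chosen_early = _pick(early_cand, EARLY_MEDIAN) if len(early_cand) else None
        chosen_late = _pick(late_cand, LATE_MEDIAN) if len(late_cand) else None
        if chosen_early is not None:
            gap = chosen_early["days_from_ici_start"] - baseline["days_from_ici_start"]
            if gap > MAX_BASELINE_GAP:
                chosen_early = None  # patient leaves the early-window analysis
        for _, r in post.iterrows():
            day = r["days_from_ici_start"]
            if chosen_early is not None and r["sample_id"] == chosen_early["sample_id"]:
                rows.append((pid, "early", r["sample_id"], day, ""))
            elif chosen_late is not None and r["sample_id"] == chosen_late["sample_id"]:
                rows.append((pid, "late", r["sample_id"], day, ""))
            else:
                if day < 7:
                    reason = "within one week of treatment start"
                elif day < EARLY[0]:
                    reason = "between 1 and 2 weeks (outside both windows)"
                elif day > LATE[1] - 1:
                    reason = "after 12 weeks"
                elif chosen_early is None and day < EARLY[1]:
                    reason = "baseline to early gap exceeds 7 weeks"
                else:
                    reason = "not closest to window median"
                rows.append((pid, "discarded", r["sample_id"], day, reason))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "window", "sample_id", "days_from_start", "reason_discarded"],
    )


def build_pairs(
    values: pd.DataFrame, assignments: pd.DataFrame, window: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and follow-up value matrices indexed by patient (paired rows)."""
    a = assignments.set_index("sample_id")
    base = a[a["window"] == "baseline"]
    follow = a[a["window"] == window]
    patients = sorted(set(base["patient_id"]) & set(follow["patient_id"]))
    base_ids = base.reset_index().set_index("patient_id").loc[patients, "sample_id"]
    fu_ids = follow.reset_index().set_index("patient_id").loc[patients, "sample_id"]
    b = values.loc[base_ids.to_numpy()].set_axis(patients, axis=0)
    f = values.loc[fu_ids.to_numpy()].set_axis(patients, axis=0)
    return b, f


def _wilcoxon(diff: np.ndarray) -> float:
    nz = diff[diff != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero")
        return 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    return float(stats.wilcoxon(nz, method=method, correction=(method == "approx")).pvalue)


def paired_shift_test(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    threshold: float | None = None,
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Paired two-sided Wilcoxon signed-rank tests per variable.

    Shift = baseline - followup; the median shift is reported on the input
    scale.  Exact null distribution for <= 25 non-zero pairs without ties,
    otherwise the tie/continuity-corrected normal approximation.
    """
    rows = []
    for var in baseline.columns:
        b, f = baseline[var], followup[var]
        ok = b.notna() & f.notna()
        if ok.sum() < min_pairs:
            warnings.warn(f"{var}: fewer than {min_pairs} complete pairs; skipped")
            continue
        diff = (b[ok] - f[ok]).to_numpy()
        p = _wilcoxon(diff)
        rows.append(
            {
                "variable": var,
                "n_pairs": int(ok.sum()),
                "median_difference": float(np.median(diff)),
                "p": p,
                "significant": bool(p < threshold) if threshold is not None else None,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def swap_permutation_validate(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    threshold: float,
    n_perm: int = 1000,
    seed: int = 0,
    variables=None,
    criterion: str = "threshold",
) -> pd.DataFrame:
    """Swap-permutation empirical p-values for paired shifts.

    Under the no-treatment-effect hypothesis the two measurements of a
    patient are exchangeable: each permutation swaps baseline and follow-up
    for a random subset of patients (independent fair coins) and recomputes
    the signed-rank test.
    """
    rng = np.random.default_rng(seed)
    if variables is None:
        variables = list(baseline.columns)
    rows = []
    for var in variables:
        b, f = baseline[var], followup[var]
        ok = b.notna() & f.notna()
        diff = (b[ok] - f[ok]).to_numpy()
        p_obs = _wilcoxon(diff)
        exceed = 0
        for _ in range(n_perm):
            signs = np.where(rng.random(len(diff)) < 0.5, -1.0, 1.0)
            p_perm = _wilcoxon(diff * signs)
            if criterion == "threshold":
                exceed += p_perm < threshold
            elif criterion == "observed":
                exceed += p_perm <= p_obs
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
        rows.append({"variable": var, "p_obs": p_obs, "eP": empirical_p(int(exceed), n_perm)})
    return pd.DataFrame(rows).set_index("variable")


def shift_vs_orr(
    shifts: pd.DataFrame,
    orr: pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of per-patient shifts with response, covariate adjusted.

    Bonferroni threshold = alpha / number of tested variables.
    """
    n_vars = shifts.shape[1]
    if n_vars == 0:
        raise ValueError("no variables to test")
    threshold = alpha / n_vars
    X_cov = build_covariate_matrix(covariates)
    common = shifts.index.intersection(X_cov.index).intersection(pd.Series(orr).index)
    rows = []
    for var in shifts.columns:
        y = shifts.loc[common, var]
        ok = y.notna()
        beta, se, p = _ols_single(
            y[ok].to_numpy(),
            pd.Series(orr).loc[common][ok].to_numpy(dtype=float),
            X_cov.loc[common][ok].to_numpy(),
        )
        rows.append(
            {
                "variable": var,
                "n": int(ok.sum()),
                "beta": beta,
                "se": se,
                "p": p,
                "threshold": threshold,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
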