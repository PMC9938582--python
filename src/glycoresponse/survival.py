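"""Cox proportional-hazards survival association for pre-treatment glycans.

One glycan at a time enters a Cox model with clinical covariates (sex, age,
BMI, dichotomised LDH, ECOG); significance comes from a likelihood-ratio test
against the covariate-only null.  The Grambsch-Therneau global chi-square
diagnostic gates a time-partitioned analysis (short < 180 d, medium 180-360 d
with delayed entry, long > 360 d) when proportional hazards fail.  Validation
permutes glycan values within quartiles of the null model's linear predictor,
preserving the covariate-outcome-glycan relationship.  Kaplan-Meier tertile
curves with log-rank tests give the graphical summary.

Partial-likelihood fits use the package's Efron Newton solver; Kaplan-Meier
estimation and log-rank tests use lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _coxlib
from .association import build_covariate_matrix
from .multiplicity import empirical_p

TERMS = ("full", "short", "medium", "long")


@dataclass
class SurvivalResult:
    variable: str
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p_lrt: float
    n: int
    n_events: int
    converged: bool
    beta: float = np.nan
    se: float = np.nan
    ph_global_p: float | None = None
    significant: bool | None = None
    eP: float | None = None
    confirmed: bool | None = None
    _X: np.ndarray = field(default=None, repr=False)
    _structure: object = field(default=None, repr=False)
    _beta_vec: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)


def _assemble(glycan: pd.Series, outcome: pd.DataFrame, covariates: pd.DataFrame | None):
    parts = [glycan.rename("glycan"), outcome[["time", "event"]]]
    if "entry" in outcome:
        parts.append(outcome["entry"])
    if covariates is not None:
        parts.append(build_covariate_matrix(covariates))
    df = pd.concat(parts, axis=1).dropna()
    X_cov = df.drop(columns=["glycan", "time", "event"], errors="ignore")
    entry = X_cov.pop("entry").to_numpy() if "entry" in X_cov else None
    constant = [c for c in X_cov.columns if X_cov[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate column(s) {constant}")
        X_cov = X_cov.drop(columns=constant)
    return df, X_cov, entry


def cox_fit(
    glycan: pd.Series,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_events: int = 10,
    term: str = "full",
) -> SurvivalResult:
    """Efron partial-likelihood fit of one glycan plus covariates.

    ``outcome`` needs columns ``time`` and ``event`` (and optionally
    ``entry`` for delayed entry).  The p-value is a likelihood-ratio test of
    the glycan term against the covariate-only null.
    """
    df, X_cov, entry = _assemble(glycan, outcome, covariates)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events")
    if n_events < min_events:
        raise ValueError(f"only {n_events} events (< floor {min_events})")
    s = _coxlib.build_structure(df["time"], df["event"], entry)
    Xc = X_cov.to_numpy(dtype=float)
    g = df["glycan"].to_numpy(dtype=float)
    if g.std() == 0:
        # degenerate covariate carries no information
        return SurvivalResult(
            variable=str(glycan.name),
            term=term,
            hr=1.0,
            ci_low=1.0,
            ci_high=1.0,
            p_lrt=1.0,
            n=len(df),
            n_events=n_events,
            converged=True,
        )
    X = np.column_stack([g, Xc])
    _, ll_null, conv_null = _coxlib.null_loglik(Xc, s)
    beta, ll_full, cov, converged = _coxlib.newton_fit(X, s)
    converged = converged and conv_null and cov is not None
    z = stats.norm.ppf(0.975)
    se = float(np.sqrt(cov[0, 0])) if cov is not None else np.nan
    b = float(beta[0])
    return SurvivalResult(
        variable=str(glycan.name),
        term=term,
        hr=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_lrt=_coxlib.lrt_pvalue(ll_full, ll_null) if converged else np.nan,
        n=len(df),
        n_events=n_events,
        converged=bool(converged),
        beta=b,
        se=se,
        _X=X,
        _structure=s,
        _beta_vec=beta,
        _cov=cov,
    )


def ph_test(fit: SurvivalResult, transform: str = "km") -> float:
    """Grambsch-Therneau global chi-square p for a converged fit."""
    if not fit.converged or fit._X is None:
        raise ValueError("PH test needs a converged fit")
    if fit._structure.n_events < 3:
        warnings.warn("fewer than 3 events; PH test skipped")
        return np.nan
    _, p = _coxlib.grambsch_therneau_global(
        fit._beta_vec, fit._X, fit._structure, fit._cov, transform=transform
    )
    fit.ph_global_p = p
    return p


def _term_dataset(outcome: pd.DataFrame, cuts=(180.0, 360.0)) -> dict:
    """Split the follow-up axis: administrative censoring + delayed entry."""
    c1, c2 = cuts
    t = outcome["time"]
    e = outcome["event"].astype(int)
    out = {}
    short = pd.DataFrame(
        {"time": t.clip(upper=c1), "event": np.where(t <= c1, e, 0)}, index=outcome.index
    )
    out["short"] = short
    at_risk_1 = t > c1
    if at_risk_1.any():
        med = pd.DataFrame(
            {
                "time": t[at_risk_1].clip(upper=c2),
                "event": np.where(t[at_risk_1] <= c2, e[at_risk_1], 0),
                "entry": c1,
            },
            index=outcome.index[at_risk_1],
        )
        out["medium"] = med
    at_risk_2 = t > c2
    if at_risk_2.any():
        out["long"] = pd.DataFrame(
            {"time": t[at_risk_2], "event": e[at_risk_2], "entry": c2},
            index=outcome.index[at_risk_2],
        )
    return out


def time_partitioned_cox(
    glycan: pd.Series,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cuts=(180.0, 360.0),
    min_events: int = 3,
) -> list:
    """Per-term Cox fits after partitioning the time axis at ``cuts``.

    Terms with no (or too few) events, or whose fit fails to converge, are
    skipped with a warning, mirroring the discard rule for sparse terms.
    """
    results = []
    for term, data in _term_dataset(outcome, cuts).items():
        if data["event"].sum() == 0:
            warnings.warn(f"term {term}: no events; skipped")
            continue
        try:
            fit = cox_fit(glycan, data, covariates, min_events=min_events, term=term)
        except ValueError as exc:
            warnings.warn(f"term {term}: {exc}; skipped")
            continue
        if not fit.converged:
            warnings.warn(f"term {term}: non-convergence; discarded")
            continue
        results.append(fit)
    return results


def _quartile_strata(lp: np.ndarray) -> np.ndarray:
    qs = np.quantile(lp, [0.25, 0.5, 0.75])
    strata = np.searchsorted(qs, lp, side="left")
    # merge strata with < 2 members into a neighbour
    for s_id in range(4):
        if 0 < (strata == s_id).sum() < 2:
            warnings.warn(f"stratum {s_id} has < 2 members; merged with neighbour")
            strata[strata == s_id] = s_id - 1 if s_id > 0 else s_id + 1
    return strata


def quartile_stratified_permutation(
    glycan: pd.Series,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None,
    threshold: float,
    n_perm: int = 5000,
    seed: int = 0,
    criterion: str = "threshold",
) -> dict:
    """Empirical p from permutations of the glycan within linear-predictor quartiles.

    The covariate-only null model's linear predictor splits the sample into
    quartiles; each permutation reshuffles glycan values within each quartile
    independently (covariates and outcomes untouched) and the model is refit.
    ``criterion="threshold"`` counts permutations whose LRT p beats the
    Bonferroni threshold; ``criterion="observed"`` counts permutations at
    least as extreme as the observed LRT p.
    """
    df, X_cov, entry = _assemble(glycan, outcome, covariates)
    s = _coxlib.build_structure(df["time"], df["event"], entry)
    Xc = X_cov.to_numpy(dtype=float)
    g = df["glycan"].to_numpy(dtype=float)
    beta_null, ll_null, conv = _coxlib.null_loglik(Xc, s)
    if not conv:
        raise ValueError("null model failed to converge")
    lp = Xc @ beta_null if Xc.shape[1] else np.zeros(len(df))
    strata = _quartile_strata(lp)

    X = np.column_stack([g, Xc])
    beta_obs, ll_obs, _, conv_obs = _coxlib.newton_fit(X, s)
    p_obs = _coxlib.lrt_pvalue(ll_obs, ll_null) if conv_obs else np.nan

    rng = np.random.default_rng(seed)
    idx_by_stratum = [np.flatnonzero(strata == k) for k in np.unique(strata)]
    exceed = 0
    Xp = X.copy()
    for _ in range(n_perm):
        gp = g.copy()
        for idx in idx_by_stratum:
            gp[idx] = gp[rng.permutation(idx)]
        Xp[:, 0] = gp
        beta_p, ll_p, _, conv_p = _coxlib.newton_fit(Xp, s, beta_init=beta_obs)
        if not conv_p:
            continue
        p_perm = _coxlib.lrt_pvalue(ll_p, ll_null)
        if criterion == "threshold":
            exceed += p_perm < threshold
        elif criterion == "observed":
            exceed += p_perm <= p_obs
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return {
        "variable": str(glycan.name),
        "p_obs": p_obs,
        "eP": empirical_p(int(exceed), n_perm),
        "strata_sizes": [len(i) for i in idx_by_stratum],
    }


def km_tertiles(glycan: pd.Series, outcome: pd.DataFrame) -> dict:
    """Kaplan-Meier curves for low/medium/high tertiles plus log-rank p."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.concat([glycan.rename("glycan"), outcome[["time", "event"]]], axis=1).dropna()
    if df["glycan"].nunique() < 3:
        raise ValueError("need at least 3 distinct glycan values")
    q1, q2 = df["glycan"].quantile([1 / 3, 2 / 3])
    labels = np.where(df["glycan"] <= q1, "low", np.where(df["glycan"] <= q2, "medium", "high"))
    if len(np.unique(labels)) < 3:
        warnings.warn("ties collapsed a tertile; falling back to a median split")
        labels = np.where(df["glycan"] <= df["glycan"].median(), "low", "high")
    curves = {}
    for grp in np.unique(labels):
        mask = labels == grp
        kmf = KaplanMeierFitter()
        kmf.fit(df["time"][mask], df["event"][mask], label=str(grp))
        sf = kmf.survival_function_
        curves[grp] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    lr = multivariate_logrank_test(df["time"], labels, df["event"])
    return {"curves": curves, "logrank_p": float(lr.p_value), "groups": labels}
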