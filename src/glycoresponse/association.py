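"""Pre-treatment glycan-response association testing.

Per variable, an ordinary least-squares model of the (inverse-normal) glycan
value on the binary response label plus clinical covariates (sex, age at
advanced-melanoma diagnosis, BMI, dichotomised LDH, ECOG performance status).
Significant hits are validated by label permutation with an add-one empirical
p-value.  A covariate-adjusted PERMANOVA (Euclidean distances, sequential
sums of squares) checks multivariate stratification of the glycome by a
grouping factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .multiplicity import empirical_p

COVARIATE_COLUMNS = ["age", "sex", "bmi", "ldh_high", "ecog"]


def build_covariate_matrix(
    covariates: pd.DataFrame, include_stage: bool = False
) -> pd.DataFrame:
    """Numeric design columns (no intercept) from the clinical covariate set.

    ECOG enters as categorical; levels with fewer than 2 patients are merged
    downwards (3 into 2+).  Metastatic stage (prediction models only) merges
    levels with fewer than 3 patients into the adjacent level.
    """
    cols = {}
    for c in ["age", "sex", "bmi", "ldh_high"]:
        cols[c] = pd.to_numeric(covariates[c])
    ecog = covariates["ecog"].astype(int).copy()
    counts = ecog.value_counts()
    for level in sorted(counts.index, reverse=True):
        if level > 0 and counts.get(level, 0) < 2:
            ecog = ecog.replace(level, level - 1)
            counts = ecog.value_counts()
    for level in sorted(ecog.unique()):
        if level == 0:
            continue
        cols[f"ecog_{level}"] = (ecog == level).astype(float)
    if include_stage and "stage" in covariates:
        stage = covariates["stage"].astype(str).copy()
        counts = stage.value_counts()
        if counts.get("III_unresectable", 0) < 3:
            stage = stage.replace("III_unresectable", "M1a")
        levels = sorted(stage.unique())
        for level in levels[1:]:
            cols[f"stage_{level}"] = (stage == level).astype(float)
    out = pd.DataFrame(cols, index=covariates.index)
    if out.isna().any().any():
        out = out.dropna()
    return out


def _ols_single(y: np.ndarray, orr: np.ndarray, X_cov: np.ndarray):
    """OLS of y on [1, orr, covariates]; returns beta, se, p for the orr term."""
    X = np.column_stack([np.ones(len(y)), orr, X_cov])
    model = sm.OLS(y, X).fit()
    return model.params[1], model.bse[1], model.pvalues[1]


def associate_orr(
    values: pd.DataFrame,
    orr: pd.Series,
    covariates: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Covariate-adjusted association of each glycan/trait with response.

    ``values`` has one row per patient (pre-treatment, transformed scale).
    Returns a results frame with beta, SE, two-sided p and a significance flag
    at ``threshold``.
    """
    orr = pd.Series(orr)
    if orr.nunique() < 2:
        raise ValueError("response label has no contrast (constant)")
    X_cov = build_covariate_matrix(covariates)
    common = values.index.intersection(X_cov.index).intersection(orr.index)
    if len(common) < X_cov.shape[1] + 3:
        raise ValueError("not enough complete cases for the model")
    results = []
    for var in values.columns:
        y = values.loc[common, var]
        ok = y.notna()
        beta, se, p = _ols_single(
            y[ok].to_numpy(),
            orr.loc[common][ok].to_numpy(dtype=float),
            X_cov.loc[common][ok].to_numpy(),
        )
        results.append(
            {
                "variable": var,
                "n": int(ok.sum()),
                "beta": beta,
                "se": se,
                "p": p,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(results).set_index("variable")


def _fwl_permutation_pvalues(
    y: np.ndarray, orr: np.ndarray, X_cov: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Two-sided OLS p-values of the orr term for every permutation (columns).

    Frisch-Waugh-Lovell: residualise y and each permuted label vector on the
    covariates (plus intercept); the t statistic of the simple regression of
    the residuals equals the full-model t exactly.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), X_cov])
    p_cov = X.shape[1]
    Q, _ = np.linalg.qr(X)
    r_y = y - Q @ (Q.T @ y)
    P = orr[perms.T]  # n x B matrix of permuted labels
    R_x = P - Q @ (Q.T @ P)
    xx = (R_x**2).sum(axis=0)
    xy = R_x.T @ r_y
    beta = xy / xx
    df = n - p_cov - 1
    rss = (r_y @ r_y) - beta**2 * xx
    se = np.sqrt(rss / df / xx)
    t = beta / se
    return 2 * stats.t.sf(np.abs(t), df)


def label_permutation_validate(
    values: pd.DataFrame,
    orr: pd.Series,
    covariates: pd.DataFrame,
    threshold: float,
    n_perm: int = 5000,
    seed: int = 0,
    variables=None,
    criterion: str = "threshold",
) -> pd.DataFrame:
    """Label-permutation empirical p-values.

    Response labels are shuffled over the whole cohort (covariates and glycan
    values fixed) and the association model refit per permutation.  With
    ``criterion="threshold"`` T counts permutations whose p-value beats the
    Bonferroni threshold (the validation construction used for the confirmed
    flags); with ``criterion="observed"`` T counts permutations at least as
    extreme as the observed p-value, giving a null-uniform eP.
    """
    rng = np.random.default_rng(seed)
    orr = pd.Series(orr)
    X_cov = build_covariate_matrix(covariates)
    common = values.index.intersection(X_cov.index).intersection(orr.index)
    if variables is None:
        variables = list(values.columns)
    rows = []
    for var in variables:
        y = values.loc[common, var]
        ok = y.notna()
        yv = y[ok].to_numpy()
        ov = orr.loc[common][ok].to_numpy(dtype=float)
        Xc = X_cov.loc[common][ok].to_numpy()
        n = len(yv)
        perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
        perm_p = _fwl_permutation_pvalues(yv, ov, Xc, perms)
        _, _, p_obs = _ols_single(yv, ov, Xc)
        if criterion == "threshold":
            t_count = int((perm_p < threshold).sum())
        elif criterion == "observed":
            t_count = int((perm_p <= p_obs).sum())
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        rows.append({"variable": var, "p_obs": p_obs, "eP": empirical_p(t_count, n_perm)})
    return pd.DataFrame(rows).set_index("variable")


def permanova(
    values: pd.DataFrame,
    grouping: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutational MANOVA on Euclidean distances of the scaled glycome.

    Sequential (covariates-first) partition of the total sum of squares in the
    McArdle-Anderson form; the pseudo-F of the grouping term is compared with
    its distribution over free permutations of the sample rows.
    """
    grouping = pd.Series(grouping)
    counts = grouping.value_counts()
    if len(counts) < 2:
        raise ValueError("grouping must have at least 2 groups")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton group(s): {bad}")
    X = values.loc[grouping.index].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            "missing values in the glycome matrix; run PERMANOVA on a complete "
            "stage (before outlier removal)"
        )
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    n = X.shape[0]
    one = np.ones((n, 1))
    if covariates is not None:
        Z = np.column_stack([one, covariates.loc[grouping.index].to_numpy(dtype=float)])
    else:
        Z = one
    G = pd.get_dummies(grouping).to_numpy(dtype=float)
    W = np.column_stack([Z, G[:, 1:]])

    def hat(M):
        Q, _ = np.linalg.qr(M)
        return Q @ Q.T

    H_cov, H_full = hat(Z), hat(W)
    df_group = len(counts) - 1
    df_resid = n - np.linalg.matrix_rank(W)

    def pseudo_f(Xm):
        ss_group = np.sum(((H_full - H_cov) @ Xm) * Xm)
        ss_resid = np.sum(Xm**2) - np.sum((H_full @ Xm) * Xm)
        return (ss_group / df_group) / (ss_resid / df_resid)

    f_obs = pseudo_f(X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(X[rng.permutation(n)]) >= f_obs:
            exceed += 1
    return {
        "pseudo_F": float(f_obs),
        "p": empirical_p(exceed, n_perm),
        "df_group": df_group,
        "df_resid": int(df_resid),
    }
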