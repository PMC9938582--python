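"""Cross-validated response prediction.

Binomial GLMs predict responder status from clinical variables (age, sex,
BMI, metastatic stage, dichotomised LDH, ECOG) alone or together with the
glycans/traits that passed the association screen.  Performance is the AUC of
the pooled leave-one-out held-out probabilities; the incremental value of the
glycan block over the clinical model is assessed by permuting the glycan rows
as a single set (preserving their intra-subject correlation) and recomputing
the full LOOCV AUC per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import build_covariate_matrix
from .multiplicity import empirical_p


@dataclass
class PredictionModelSpec:
    name: str  # clinical | clinical+measured | clinical+derived
    glycan_terms: tuple = ()
    include_stage: bool = True


@dataclass
class AUCResult:
    model: str
    auc: float
    n: int
    predictions: pd.Series = field(repr=False, default=None)
    eP_contribution: float | None = None


def _logit_irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 50):
    """Newton/IRLS logistic fit; returns (beta, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            # quasi-separation shows up as runaway coefficients
            if ridge == 0.0 and np.max(np.abs(beta)) > 15:
                return beta, False
            return beta, True
    return beta, False


def _fit_fold(X, y, ridge_fallback=1e-4, warn=True):
    beta, ok = _logit_irls(X, y)
    if not ok:
        if warn:
            warnings.warn("separation or non-convergence; ridge-stabilised fit used")
        beta, _ = _logit_irls(X, y, ridge=ridge_fallback)
    return beta


def rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formula with tie correction."""
    y = np.asarray(y)
    ranks = stats.rankdata(score)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both cases and controls")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _design(data: pd.DataFrame, spec: PredictionModelSpec):
    cov = build_covariate_matrix(data, include_stage=spec.include_stage)
    blocks = [cov]
    if spec.glycan_terms:
        blocks.append(data[list(spec.glycan_terms)])
    X = pd.concat(blocks, axis=1).dropna()
    y = data.loc[X.index, "orr"].astype(int)
    return X, y


def loocv_auc(spec: PredictionModelSpec, data: pd.DataFrame, _glycan_override=None) -> AUCResult:
    """Leave-one-out cross-validated AUC of the model given by ``spec``.

    ``data`` holds one row per patient with clinical columns, ``orr``, and any
    glycan term columns (already on their analysis scale).
    """
    X_df, y_s = _design(data, spec)
    X = np.column_stack([np.ones(len(X_df)), X_df.to_numpy(dtype=float)])
    if _glycan_override is not None:
        # replace the trailing glycan block (used by the permutation loop)
        X[:, -_glycan_override.shape[1] :] = _glycan_override
    y = y_s.to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    n = len(y)
    beta_full = _fit_fold(X, y, warn=False)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        beta, ok = _logit_irls(X[mask], y[mask])
        if not ok:
            beta, _ = _logit_irls(X[mask], y[mask], ridge=1e-4)
        preds[i] = 1.0 / (1.0 + np.exp(-np.clip(X[i] @ beta, -30, 30)))
        mask[i] = True
    _ = beta_full
    auc = rank_auc(y, preds)
    return AUCResult(
        model=spec.name, auc=auc, n=n, predictions=pd.Series(preds, index=X_df.index)
    )


def block_permutation_contribution(
    spec: PredictionModelSpec,
    data: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical p for the glycan block's contribution to the LOOCV AUC.

    Per permutation one shared reshuffle reassigns the rows of the glycan
    sub-matrix to patients (clinical columns untouched), preserving the
    glycans' mutual correlation; eP = P(AUC_perm >= AUC_obs) with the add-one
    rule.
    """
    if not spec.glycan_terms:
        raise ValueError("spec has no glycan terms")
    obs = loocv_auc(spec, data)
    X_df, _ = _design(data, spec)
    glycan_block = X_df[list(spec.glycan_terms)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = glycan_block.shape[0]
    exceed = 0
    perm_aucs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_perm):
            perm = rng.permutation(n)
            res = loocv_auc(spec, data, _glycan_override=glycan_block[perm])
            perm_aucs.append(res.auc)
            if res.auc >= obs.auc:
                exceed += 1
    return {
        "model": spec.name,
        "auc_obs": obs.auc,
        "eP": empirical_p(exceed, n_perm),
        "perm_auc_mean": float(np.mean(perm_aucs)),
    }
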