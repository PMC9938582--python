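"""Parametric empirical-Bayes batch correction (location/scale model).

Standard ComBat algorithm: per-feature standardisation, per-batch location
(gamma) and scale (delta^2) estimates shrunk towards normal / inverse-gamma
priors whose hyperparameters are estimated across features by the method of
moments, solved by the usual fixed-point iteration, then adjustment and
restoration of the overall location/scale.  Batch-only design (no model
covariates).
"""

from __future__ import annotations

import numpy as np


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Fixed-point iteration for the EB-shrunk batch location/scale."""
    n = (~np.isnan(sdat)).sum(axis=0).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = np.nansum((sdat - g_new) ** 2, axis=0)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(data: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Adjust ``data`` (samples x features) for ``batch`` effects.

    Returns the corrected array; a single batch is returned unchanged.
    NaN cells are tolerated and left NaN.
    """
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    levels, inverse = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    if n_batch == 1:
        return data.copy()
    counts = np.bincount(inverse)
    if counts.min() < 2:
        bad = levels[counts.argmin()]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")
    if not np.isfinite(np.nan_to_num(data, nan=0.0)).all():
        raise ValueError("non-finite values in input")

    n_total = data.shape[0]
    batch_masks = [inverse == b for b in range(n_batch)]

    # grand mean weighted by batch size; pooled variance of the batch-centred data
    batch_means = np.vstack([np.nanmean(data[m], axis=0) for m in batch_masks])
    grand_mean = (counts[:, None] * batch_means).sum(axis=0) / n_total
    resid = data - batch_means[inverse]
    var_pooled = np.nansum(resid**2, axis=0) / n_total
    var_pooled = var_pooled.clip(min=1e-18)

    z = (data - grand_mean) / np.sqrt(var_pooled)

    gamma_star = np.empty((n_batch, data.shape[1]))
    delta_star = np.empty((n_batch, data.shape[1]))
    for b, mask in enumerate(batch_masks):
        sdat = z[mask]
        g_hat = np.nanmean(sdat, axis=0)
        d_hat = np.nanvar(sdat, axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, bprior = _aprior(d_hat), _bprior(d_hat)
        gamma_star[b], delta_star[b] = _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, bprior)

    adjusted = (z - gamma_star[inverse]) / np.sqrt(delta_star[inverse])
    return adjusted * np.sqrt(var_pooled) + grand_mean
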