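"""Multiple-testing effective dimension, power, and empirical p-values.

The effective number of independent tests follows the eigenvalue-spectrum
correction of Li & Ji: N_eff = sum_i f(|lambda_i|) with
f(x) = I(x >= 1) + (x - floor(x)), computed on the correlation matrix of the
tested variables.  Power for a two-group mean difference uses the exact
noncentral-t distribution.  The add-one empirical p-value
eP = (T + 1)/(B + 1) is shared by all permutation stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MultiplicityResult:
    n_eff_raw: float
    n_eff_reported: int
    alpha: float
    threshold: float


def li_ji_neff(correlation_matrix, alpha: float = 0.05) -> MultiplicityResult:
    """Effective number of independent tests from a correlation matrix."""
    c = np.asarray(correlation_matrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.abs(np.linalg.eigvalsh(c))
    # f has jumps at the integers; snap eigenvalues that are integer up to
    # numerical noise so degenerate matrices (identity, rank one) are exact
    near = np.abs(lam - np.round(lam)) < 1e-9 * max(1.0, lam.max())
    lam = np.where(near, np.round(lam), lam)
    f = (lam >= 1).astype(float) + (lam - np.floor(lam))
    n_eff_raw = float(f.sum())
    # round half away from zero, matching integer reporting conventions
    n_eff_reported = int(math.floor(n_eff_raw + 0.5))
    return MultiplicityResult(
        n_eff_raw=n_eff_raw,
        n_eff_reported=n_eff_reported,
        alpha=alpha,
        threshold=alpha / n_eff_reported,
    )


def correlation_for_neff(values, method: str = "pearson") -> np.ndarray:
    """Pairwise-complete correlation matrix of a samples-by-variables table."""
    import pandas as pd

    df = pd.DataFrame(values)
    return df.corr(method=method, min_periods=3).to_numpy()


def two_sample_power(n1: int, n2: int, d: float, alpha: float) -> float:
    """Power of a two-sided two-sample t-test at Cohen's d (noncentral t)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if d < 0:
        raise ValueError("d must be non-negative")
    df = n1 + n2 - 2
    ncp = d / math.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def empirical_p(t_exceed: int, n_perm: int) -> float:
    """Add-one empirical p-value (T + 1)/(B + 1); never returns 0."""
    if not 0 <= t_exceed <= n_perm:
        raise ValueError("need 0 <= t_exceed <= n_perm")
    return (t_exceed + 1) / (n_perm + 1)
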