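"""Small closed-form OLS helper shared by the linearity and stability fits.

Kept dependency-light (numpy + scipy.stats only) because the Monte-Carlo
property suites refit thousands of small regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "ols"]


@dataclass(frozen=True)
class OLSFit:
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    sigma: float          # residual standard error
    df_resid: int
    xtx_inv: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta

    def se_mean(self, X: np.ndarray) -> np.ndarray:
        """Standard error of the fitted mean at rows of X."""
        return self.sigma * np.sqrt(np.einsum("ij,jk,ik->i", X, self.xtx_inv, X))


def ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares with per-coefficient two-sided t-tests.

    Degenerate zero-residual fits are handled explicitly: a coefficient
    that is exactly zero gets p = 1, any nonzero coefficient p = 0 (the
    data determine the line without error).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} observations for a {p}-parameter fit")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    resid = y - X @ beta
    df_resid = n - p
    rss = float(resid @ resid)
    # guard against catastrophic-cancellation noise in exact fits
    tss = float(((y - y.mean()) ** 2).sum())
    if rss <= 1e-12 * max(tss, 1.0):
        rss = 0.0
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    if sigma2 == 0.0:
        p_values = np.where(np.isclose(beta, 0.0), 1.0, 0.0)
    else:
        t = beta / se
        p_values = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return OLSFit(beta=beta, se=se, p_values=p_values,
                  sigma=float(np.sqrt(sigma2)), df_resid=df_resid,
                  xtx_inv=xtx_inv)
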