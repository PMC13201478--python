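"""Maximum-likelihood logistic regression via iteratively reweighted least squares.

This is the numerical core shared by the single-metal association models, the
restricted-cubic-spline dose-response fits, and the WQS bootstrap loop.  The
solver is deliberately small and allocation-light: the WQS procedure refits
the same three-column model thousands of times on bootstrap resamples, where
per-call overhead of a full model framework would dominate the runtime.

Convergence contract: Newton/IRLS steps until ``max |score| < 1e-8`` or the
relative change in log-likelihood falls below ``1e-10``, with a hard cap of
100 iterations.  Wald standard errors come from the inverse observed
information at the optimum.  Quasi-complete separation shows up as fitted
probabilities collapsing to 0/1 and diverging coefficients; it is flagged via
``converged=False`` rather than raised, so callers can drop or report the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "fit_logistic"]

_SCORE_TOL = 1e-8
_LLF_RTOL = 1e-10
_MAX_ITER = 100


@dataclass
class LogisticFit:
    """A fitted binary logistic model.

    Attributes
    ----------
    params : ndarray
        Coefficient vector, in the column order of the design matrix
        (the caller supplies the intercept column).
    cov_params : ndarray
        Inverse observed information; Wald covariance of ``params``.
    llf : float
        Log-likelihood at the optimum.
    n_used : int
        Number of rows in the fit.
    converged : bool
        False when the iteration cap was hit or the fit diverged
        (typically separation).
    n_iter : int
        Newton iterations performed.
    """

    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    n_used: int
    converged: bool
    n_iter: int = 0

    @property
    def bse(self) -> np.ndarray:
        """Wald standard errors."""
        return np.sqrt(np.diag(self.cov_params))

    def wald_ci(self, index: int, z: float = 1.959963984540054):
        """(low, high) Wald interval for one coefficient on the linear scale."""
        b, se = self.params[index], self.bse[index]
        return b - z * se, b + z * se

    def wald_p(self, index: int) -> float:
        """Two-sided Wald p-value for one coefficient."""
        from scipy import stats

        se = self.bse[index]
        if se == 0:
            return float("nan")
        z = self.params[index] / se
        return float(2.0 * stats.norm.sf(abs(z)))


def _check_design(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match design rows")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")


def fit_logistic(X, y, *, check: bool = True) -> LogisticFit:
    """Fit a binary logistic regression by Newton-Raphson (IRLS).

    Parameters
    ----------
    X : (n, p) array_like
        Design matrix including an intercept column if one is wanted.
    y : (n,) array_like
        Binary outcome coded 0/1.
    check : bool
        Validate inputs (binary outcome, full rank).  The WQS inner loop
        disables this after validating once up front.

    Returns
    -------
    LogisticFit

    Raises
    ------
    numpy.linalg.LinAlgError
        If the design matrix is rank deficient.
    ValueError
        On malformed inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if check:
        _check_design(X, y)
    n, p = X.shape

    beta = np.zeros(p)
    # Intercept warm start: logit of the observed prevalence, clipped away
    # from the boundary so all-0/all-1 outcomes fail gracefully.
    pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta[0] = np.log(pbar / (1 - pbar)) if np.allclose(X[:, 0], 1.0) else 0.0

    llf_old = -np.inf
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # Step-halving keeps the likelihood monotone near separation.
        llf = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        new_beta = beta + step
        for _ in range(20):
            eta_n = X @ new_beta
            mu_n = np.clip(expit(eta_n), 1e-12, 1 - 1e-12)
            llf_n = float(y @ np.log(mu_n) + (1 - y) @ np.log1p(-mu_n))
            if llf_n >= llf or not np.isfinite(llf_n):
                break
            step *= 0.5
            new_beta = beta + step
        beta = new_beta
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        if np.isfinite(llf_n) and llf_old > -np.inf:
            if abs(llf_n - llf_old) <= _LLF_RTOL * (abs(llf_old) + _LLF_RTOL):
                converged = True
                break
        llf_old = llf_n

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    llf = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    # Separation diagnostics: diverging coefficients, a (near-)perfect fit,
    # or a flat likelihood direction (absurd Wald SEs under
    # quasi-separation) all mark the fit unusable.
    diag = np.diag(cov)
    if (
        np.max(np.abs(beta)) > 1e2
        or llf > -1e-8 * n
        or (np.all(np.isfinite(diag)) and np.any(diag > 1e6))
    ):
        converged = False
    return LogisticFit(
        params=beta, cov_params=cov, llf=llf, n_used=n, converged=converged, n_iter=it
    )
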