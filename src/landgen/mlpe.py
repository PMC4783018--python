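"""Mixed-effects model fits for pairwise distance data and AICc ranking.

Pairwise observations are not independent: two pairs that share an individual
are correlated.  The maximum-likelihood population effects (MLPE) covariance
structure captures this with a single correlation parameter rho applying to
every pair of observations sharing exactly one individual.  Genetic distance
is regressed on standardized effective distance under this structure by
maximum likelihood (not REML, so models with different fixed effects are
AICc-comparable), and competing resistance hypotheses — always including the
isolation-by-distance null — are ranked by AICc and Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genetics import DistanceMatrix

RHO_MAX = 0.499  # the MLPE bound is 0.5; stop just inside for invertibility


class ModelError(ValueError):
    pass


@dataclass
class MLPEFit:
    beta: float
    intercept: float
    rho: float
    sigma2: float
    loglik: float
    k: int
    n_pairs: int
    beta_se: float
    converged: bool
    labels: tuple
    response_checksum: float

    def ci95(self) -> tuple[float, float]:
        return self.beta - 1.96 * self.beta_se, self.beta + 1.96 * self.beta_se


def pair_incidence(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower-triangle pair index arrays (i, j) and the N x n incidence A."""
    i, j = np.tril_indices(n, k=-1)
    N = i.size
    A = np.zeros((N, n))
    A[np.arange(N), i] = 1.0
    A[np.arange(N), j] = 1.0
    return i, j, A


def _profile_loglik(rho, y, X, A, AtA, return_fit=False):
    """ML log-likelihood profiled over (coefs, sigma2) at fixed rho.

    The covariance is sigma2 * (c I + rho A A') with c = 1 - 2 rho; the
    Woodbury identity reduces every solve to the n x n individual block.
    """
    N, n = A.shape
    c = 1.0 - 2.0 * rho
    M = c * np.eye(n) + rho * AtA

    def siginv(V):
        # (1/c) (V - rho A M^{-1} A' V)
        return (V - rho * (A @ np.linalg.solve(M, A.T @ V))) / c

    Wy = siginv(y)
    WX = siginv(X)
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    coef = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ coef
    quad = float(resid @ siginv(resid))
    sigma2 = quad / N
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0 or sigma2 <= 0:
        return -np.inf if not return_fit else (None, -np.inf)
    logdet = (N - n) * np.log(c) + logdetM
    ll = -0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + N)
    if not return_fit:
        return ll
    cov_coef = sigma2 * np.linalg.inv(XtWX)
    return (coef, sigma2, cov_coef), ll


def mlpe_fit(genetic: DistanceMatrix, effective: DistanceMatrix) -> MLPEFit:
    """ML fit of genetic distance on standardized effective distance.

    y_ij = mu + beta * z(x_ij) + e_ij with cov(e_ij, e_kl) = rho*sigma2 when
    the pairs share exactly one individual, sigma2 when identical, else 0.
    rho is profiled over [0, 0.5) by bounded scalar optimization.
    """
    if genetic.labels != effective.labels:
        raise ModelError("genetic and effective matrices have mismatched labels")
    n = genetic.n
    i, j, A = pair_incidence(n)
    y = genetic.values[i, j]
    x = effective.values[i, j]
    if not np.all(np.isfinite(x)):
        raise ModelError("effective distances contain non-finite entries")
    sd = x.std()
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    X = np.column_stack([np.ones_like(z), z])
    AtA = A.T @ A

    neg = lambda rho: -_profile_loglik(rho, y, X, A, AtA)
    res = minimize_scalar(neg, bounds=(0.0, RHO_MAX), method="bounded",
                          options={"xatol": 1e-6})
    rho_hat = float(res.x)
    # guard against a local dip: coarse grid fallback
    grid = np.linspace(0.0, RHO_MAX, 21)
    grid_ll = np.array([_profile_loglik(r, y, X, A, AtA) for r in grid])
    if grid_ll.max() > -res.fun + 1e-8:
        r0 = float(grid[int(grid_ll.argmax())])
        lo = max(0.0, r0 - 0.05)
        hi = min(RHO_MAX, r0 + 0.05)
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        rho_hat = float(res.x)
    (coef, sigma2, cov_coef), ll = _profile_loglik(rho_hat, y, X, A, AtA, return_fit=True)
    if coef is None:
        raise ModelError("MLPE fit failed to converge")
    return MLPEFit(
        beta=float(coef[1]),
        intercept=float(coef[0]),
        rho=rho_hat,
        sigma2=float(sigma2),
        loglik=float(ll),
        k=4,  # intercept, slope, rho, sigma2
        n_pairs=int(y.size),
        beta_se=float(np.sqrt(cov_coef[1, 1])),
        converged=bool(res.success),
        labels=tuple(genetic.labels),
        response_checksum=float(np.sum(y) + np.sum(y**2)),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ModelError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_models(fits: dict[str, MLPEFit]) -> pd.DataFrame:
    """AICc model table (Model, LogLik, K, AICc, dAICc, AICcWt), best first.

    All fits must be on the identical response (same individuals, same
    genetic distances); non-converged fits are dropped with a warning column.
    """
    if not fits:
        raise ModelError("no fits supplied")
    ref = next(iter(fits.values()))
    for name, f in fits.items():
        if f.labels != ref.labels or abs(f.response_checksum - ref.response_checksum) > 1e-6 * max(
            1.0, abs(ref.response_checksum)
        ):
            raise ModelError(f"fit {name!r} was made on different response data")
    usable = {k: f for k, f in fits.items() if f.converged}
    if not usable:
        raise ModelError("no converged fits")
    rows = []
    for name, f in usable.items():
        rows.append((name, f.loglik, f.k, aicc(f.loglik, f.k, f.n_pairs)))
    df = pd.DataFrame(rows, columns=["Model", "LogLik", "K", "AICc"])
    df = df.sort_values("AICc", kind="mergesort").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["AICcWt"] = akaike_weights(df["AICc"].to_numpy())
    return df
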