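"""Single-kinship linear mixed model fitted via eigendecomposition.

Model: y = X b + u + e, u ~ N(0, sigma_g2 * K), e ~ N(0, sigma_e2 * I).
Eigendecomposing K once turns every evaluation of the (restricted) likelihood
over the variance ratio delta = sigma_e2 / sigma_g2 into O(n) work on rotated
data — the trick association scans use to fix variance components once and
test markers by generalized least squares.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize_scalar


@dataclasses.dataclass
class KinshipEigen:
    values: np.ndarray  # ascending eigenvalues, clipped at 0
    vectors: np.ndarray

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipEigen":
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        vals, vecs = np.linalg.eigh(K)
        if vals[0] < -1e-6 * max(vals[-1], 1.0):
            raise ValueError("kinship matrix is not positive semi-definite")
        return cls(values=np.clip(vals, 0.0, None), vectors=vecs)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.vectors.T @ M


@dataclasses.dataclass
class LMMFit:
    beta: np.ndarray            # fixed-effect coefficients (GLS at delta_hat)
    delta: float                # sigma_e2 / sigma_g2
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    loglik_ml: float
    eig: KinshipEigen
    y_rot: np.ndarray
    X_rot: np.ndarray


def _profile(y_rot, X_rot, lam, delta, restricted: bool):
    """Profile (restricted) log-likelihood at a given variance ratio."""
    n, p = X_rot.shape
    w = lam + delta
    Dinv = 1.0 / w
    XtDX = X_rot.T @ (Dinv[:, None] * X_rot)
    XtDy = X_rot.T @ (Dinv * y_rot)
    beta = np.linalg.solve(XtDX, XtDy)
    resid = y_rot - X_rot @ beta
    rss = float(resid @ (Dinv * resid))
    if restricted:
        dof = n - p
        sigma_g2 = rss / dof
        sign, logdet = np.linalg.slogdet(XtDX)
        _, logdet0 = np.linalg.slogdet(X_rot.T @ X_rot)
        ll = -0.5 * (
            dof * np.log(2 * np.pi * sigma_g2)
            + np.sum(np.log(w))
            + logdet
            - logdet0
            + dof
        )
    else:
        dof = n
        sigma_g2 = rss / dof
        ll = -0.5 * (dof * np.log(2 * np.pi * sigma_g2) + np.sum(np.log(w)) + dof)
    return ll, beta, sigma_g2


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray | None = None,
    K: np.ndarray | None = None,
    eig: KinshipEigen | None = None,
    restricted: bool = True,
    log_delta_range: tuple[float, float] = (-10.0, 10.0),
    grid: int = 64,
) -> LMMFit:
    """REML (or ML) fit by 1-D optimization of the variance ratio.

    A coarse grid over log(delta) locates the basin; Brent refines it. Both
    variance components are recovered from the profiled scale.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = KinshipEigen.from_kinship(K)
    lam = eig.values
    y_rot = eig.rotate(y)
    X_rot = eig.rotate(X)

    def negll(log_delta: float) -> float:
        ll, _, _ = _profile(y_rot, X_rot, lam, np.exp(log_delta), restricted)
        return -ll

    lo, hi = log_delta_range
    grid_pts = np.linspace(lo, hi, grid)
    vals = np.array([negll(g) for g in grid_pts])
    i = int(np.argmin(vals))
    bl = grid_pts[max(i - 1, 0)]
    br = grid_pts[min(i + 1, grid - 1)]
    res = minimize_scalar(negll, bounds=(bl, br), method="bounded",
                          options={"xatol": 1e-10})
    log_delta = float(res.x) if res.fun <= vals[i] else float(grid_pts[i])
    delta = float(np.exp(log_delta))
    ll_reml, beta, sigma_g2 = _profile(y_rot, X_rot, lam, delta, restricted=True)
    ll_ml, beta_ml, sigma_g2_ml = _profile(y_rot, X_rot, lam, delta, restricted=False)
    if not restricted:
        beta, sigma_g2 = beta_ml, sigma_g2_ml
    return LMMFit(
        beta=beta,
        delta=delta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_g2 * delta),
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        eig=eig,
        y_rot=y_rot,
        X_rot=X_rot,
    )
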