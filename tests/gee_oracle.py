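"""Independently coded exchangeable-GEE oracle (Liang-Zeger IRLS).

Kept deliberately separate from the package: a brute-force reference
solver used only to validate the library-backed fit.
"""

from __future__ import annotations

import numpy as np


def gee_exchangeable_oracle(
    y, X, clusters, tol: float = 1e-12, maxiter: int = 200
):
    """Gaussian identity-link GEE with exchangeable working correlation.

    Returns (beta, robust_se, alpha).  Moment estimators: dispersion
    sum(r^2)/(N-p); alpha from within-cluster residual cross-products
    with an (npairs - p) denominator; sandwich covariance
    B^{-1} M B^{-1}.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    ids = np.asarray(clusters)
    groups = [np.where(ids == g)[0] for g in np.unique(ids)]
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha = 0.0
    for _ in range(maxiter):
        r = y - X @ beta
        scale = np.sum(r**2) / (n - p)
        num, npair = 0.0, 0
        for idx in groups:
            rc = r[idx] / np.sqrt(scale)
            m = len(idx)
            if m > 1:
                num += (rc.sum() ** 2 - (rc**2).sum()) / 2
                npair += m * (m - 1) // 2
        alpha = num / (npair - p) if npair > p else 0.0
        A = np.zeros((p, p))
        b = np.zeros(p)
        for idx in groups:
            m = len(idx)
            R = (1 - alpha) * np.eye(m) + alpha * np.ones((m, m))
            Vinv = np.linalg.inv(R * scale)
            Xc = X[idx]
            A += Xc.T @ Vinv @ Xc
            b += Xc.T @ Vinv @ y[idx]
        new = np.linalg.solve(A, b)
        done = np.max(np.abs(new - beta)) < tol
        beta = new
        if done:
            break
    r = y - X @ beta
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for idx in groups:
        m = len(idx)
        R = (1 - alpha) * np.eye(m) + alpha * np.ones((m, m))
        Vinv = np.linalg.inv(R * scale)
        Xc = X[idx]
        u = Xc.T @ Vinv @ r[idx]
        B += Xc.T @ Vinv @ Xc
        M += np.outer(u, u)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv
    return beta, np.sqrt(np.diag(cov)), alpha
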