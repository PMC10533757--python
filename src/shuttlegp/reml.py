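"""EM-REML for mixed models with i.i.d. random-effect terms.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma_k^2 I) and
e ~ N(0, sigma_e^2 I) by EM on Henderson's mixed-model equations,
converging on the relative change of the REML log-likelihood (computed from
the same Cholesky factor the update needs).  This covers the nested-design variance decomposition
(genotype, genotype-within-location, incomplete block) and the block-variance
step of the per-trial adjusted-mean (BLUE) model.

The MME coefficient matrix is built once from indicator cross-products and
re-solved per iteration; variance estimates are kept non-negative by
projection to a small positive floor (reported as 0 if they finish there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RemlFit:
    """Estimates from :func:`em_reml`."""

    sigma2: dict            # term name -> variance estimate (0 if at boundary)
    sigma2_e: float
    beta: np.ndarray        # fixed-effect solutions (last iterate)
    u: dict                 # term name -> BLUP solutions at the estimates
    converged: bool
    n_iter: int
    loglike: float | None = None

    def variance_table(self) -> dict:
        out = dict(self.sigma2)
        out["residual"] = self.sigma2_e
        return out


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_terms: dict,
    tol: float = 1e-6,
    max_iter: int = 500,
    compute_loglike: bool = False,
) -> RemlFit:
    """EM-REML on the mixed-model equations.

    Parameters
    ----------
    y, X : response and fixed-effect design (full column rank assumed after
        internal rank check; collinear columns are dropped).
    Z_terms : mapping term name -> (n x q_k) indicator/design matrix.
    tol : relative-change convergence tolerance on the variance vector.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    # drop collinear fixed-effect columns (QR pivot-free rank check)
    q_fixed, r_fixed = np.linalg.qr(X)
    keep = np.abs(np.diag(r_fixed)) > 1e-8 * max(1.0, np.abs(np.diag(r_fixed)).max())
    if keep.size and not keep.all():
        X = X[:, keep]
    p = X.shape[1]
    names = list(Z_terms)
    Zs = [np.asarray(Z_terms[k], float) for k in names]
    qs = [Z.shape[1] for Z in Zs]
    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    from scipy.linalg import cho_factor, cho_solve

    vy = float(np.var(y)) or 1.0
    floor = 1e-8 * vy
    sig = np.full(len(names), vy / (len(names) + 1))
    sig_e = vy / (len(names) + 1)
    offsets = np.cumsum([p] + qs)
    eye = np.eye(WtW.shape[0])

    def _step(sig_vec, sig_e_val):
        """One EM update; returns new variances and -2 REML loglik (to const)."""
        M = WtW.copy()
        for k in range(len(names)):
            i0, i1 = offsets[k], offsets[k + 1]
            M[i0:i1, i0:i1] += (sig_e_val / sig_vec[k]) * np.eye(qs[k])
        c, low = cho_factor(M, lower=True)
        logdet_m = 2.0 * np.sum(np.log(np.diag(c)))
        Minv = cho_solve((c, low), eye)
        s = Minv @ Wty
        ypy = max(yty - s @ Wty, 0.0) / sig_e_val
        m2ll = ((n - p) * np.log(sig_e_val)
                + sum(qs[k] * np.log(sig_vec[k] / sig_e_val) for k in range(len(names)))
                + logdet_m + ypy)
        new_sig = np.empty_like(sig_vec)
        for k in range(len(names)):
            i0, i1 = offsets[k], offsets[k + 1]
            u_k = s[i0:i1]
            tr = np.trace(Minv[i0:i1, i0:i1])
            new_sig[k] = (u_k @ u_k + sig_e_val * tr) / qs[k]
        new_sig_e = (yty - s @ Wty) / max(n - p, 1)  # saturated fixed part -> floor
        return np.maximum(new_sig, floor), max(new_sig_e, floor), m2ll

    converged = False
    prev_m2ll = None
    it = 0
    for it in range(1, max_iter + 1):
        new_sig, new_sig_e, m2ll = _step(sig, sig_e)
        sig, sig_e = new_sig, float(new_sig_e)
        # converge on the relative change of the REML log-likelihood
        if prev_m2ll is not None and abs(prev_m2ll - m2ll) < tol * (abs(m2ll) + 1.0):
            converged = True
            break
        prev_m2ll = m2ll

    # final solve at the converged estimates
    M = WtW.copy()
    for k in range(len(names)):
        i0, i1 = offsets[k], offsets[k + 1]
        M[i0:i1, i0:i1] += (sig_e / sig[k]) * np.eye(qs[k])
    s = np.linalg.solve(M, Wty)
    beta = s[:p]
    u = {names[k]: s[offsets[k]:offsets[k + 1]] for k in range(len(names))}
    sig_out = {names[k]: (0.0 if sig[k] <= 2 * floor else float(sig[k]))
               for k in range(len(names))}

    ll = None
    if compute_loglike:
        V = sig_e * np.eye(n)
        for k, Z in enumerate(Zs):
            V += sig[k] * (Z @ Z.T)
        sign, logdetV = np.linalg.slogdet(V)
        Vinv = np.linalg.inv(V)
        XtVinvX = X.T @ Vinv @ X
        sign2, logdetX = np.linalg.slogdet(XtVinvX)
        bhat = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
        r = y - X @ bhat
        ll = -0.5 * (logdetV + logdetX + r @ Vinv @ r + (n - p) * np.log(2 * np.pi))
    return RemlFit(sig_out, float(sig_e), beta, u, converged, it, ll)


def indicator(levels) -> tuple[np.ndarray, list]:
    """Full indicator matrix (n x q) for a categorical vector, with level order."""
    import pandas as pd

    cat = pd.Categorical(levels)
    Z = np.zeros((len(cat), len(cat.categories)))
    Z[np.arange(len(cat)), cat.codes] = 1.0
    return Z, list(cat.categories)
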