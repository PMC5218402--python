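"""Random-intercept linear mixed model by profile REML.

The only random term anywhere in the analysis is a single intercept per
mother, so V = sigma2 * (I + lam * Z Z') is block diagonal and every
quantity has a closed form per group. The restricted likelihood is profiled
down to the one ratio lam = tau2/sigma2 and maximized by bounded scalar
search, which is deterministic and robust at the tau2 = 0 boundary — the
model is refit thousands of times during simplification and permutation
bookkeeping, so a flaky iterative optimizer is not acceptable here.

GLS estimates, the fixed-coefficient covariance, BLUPs and the restricted
log-likelihood all come from the same closed forms, so likelihoods of
models with and without the random term are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["RandomInterceptFit", "fit_random_intercept"]


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: float
    sigma2: float
    loglik: float                   # restricted log-likelihood
    blups: dict
    rss: float                      # ||y - X beta - Z gamma||^2

    @property
    def pss(self) -> float:
        """Penalised residual sum of squares at the REML solution."""
        if self.tau2 <= 0:
            return self.rss
        g2 = sum(v ** 2 for v in self.blups.values())
        return self.rss + (self.sigma2 / self.tau2) * g2


def _group_stats(y, X, codes, n_groups):
    """Per-group sums used by every Woodbury-style closed form."""
    n, p = X.shape
    sx = np.zeros((n_groups, p))
    sy = np.zeros(n_groups)
    ng = np.zeros(n_groups)
    np.add.at(sx, codes, X)
    np.add.at(sy, codes, y)
    np.add.at(ng, codes, 1.0)
    return sx, sy, ng


def _profile(lam, y, X, sx, sy, ng, XtX, Xty, yty):
    """Profile restricted loglik at ratio lam plus the GLS pieces."""
    n, p = X.shape
    w = lam / (1.0 + ng * lam)              # (groups,)
    A = XtX - (w[:, None] * sx).T @ sx      # X' (I+lam ZZ')^-1 X
    b = Xty - sx.T @ (w * sy)
    q = yty - float(sy @ (w * sy))
    beta = np.linalg.solve(A, b)
    quad = q - float(b @ beta)              # r' (I+lam ZZ')^-1 r at GLS beta
    sigma2 = quad / (n - p)
    logdetM = float(np.sum(np.log1p(ng * lam)))
    sign, logdetA = np.linalg.slogdet(A)
    ll = -0.5 * (n * np.log(sigma2) + logdetM
                 + logdetA - p * np.log(sigma2)
                 + (n - p)
                 + (n - p) * np.log(2 * np.pi))
    return ll, beta, A, sigma2


def fit_random_intercept(y, X, groups, max_ratio: float = 1e3) -> RandomInterceptFit:
    """REML fit of y = X beta + Z gamma + e with one intercept per group."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    codes, uniq = pd.factorize(np.asarray(groups))
    G = len(uniq)
    sx, sy, ng = _group_stats(y, X, codes, G)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def neg(loglam):
        ll, *_ = _profile(np.exp(loglam), y, X, sx, sy, ng, XtX, Xty, yty)
        return -ll

    ll0, beta0, A0, s20 = _profile(0.0, y, X, sx, sy, ng, XtX, Xty, yty)
    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-8), np.log(max_ratio)),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    ll1, beta1, A1, s21 = _profile(lam, y, X, sx, sy, ng, XtX, Xty, yty)
    if ll0 >= ll1:                          # boundary solution tau2 = 0
        lam, ll, beta, A, sigma2 = 0.0, ll0, beta0, A0, s20
    else:
        ll, beta, A, sigma2 = ll1, beta1, A1, s21
    tau2 = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)
    # BLUP per group: shrunken group-mean residual of the fixed part
    rfix = y - X @ beta
    sr = np.zeros(G)
    np.add.at(sr, codes, rfix)
    shrink = lam / (1.0 + ng * lam)
    gam = shrink * sr
    blups = {g: float(v) for g, v in zip(uniq, gam)}
    resid = rfix - gam[codes]
    return RandomInterceptFit(beta=beta, cov_beta=cov_beta, tau2=tau2,
                              sigma2=sigma2, loglik=float(ll), blups=blups,
                              rss=float(resid @ resid))
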