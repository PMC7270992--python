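"""Maximum-likelihood linear mixed models with nested random intercepts.

The association scan fits thousands of small models of the form

    y = X beta + a_family + b_subject + eps,
    a ~ N(0, tau_f^2), b ~ N(0, tau_s^2), eps ~ N(0, sigma^2),

with subjects nested in families (the family term is optional).  For this
structure beta and sigma^2 profile out of the likelihood in closed form, and
the covariance

    V = sigma^2 (I + l_f Z_f Z_f' + l_s Z_s Z_s'),   l = tau^2 / sigma^2,

has an analytic inverse: a Sherman-Morrison step per subject followed by one
per family, so every likelihood evaluation reduces to segment sums over
subject and family labels — no matrix factorisations.  Only the one or two
variance ratios are optimized numerically, which makes each fit exact for
the model and fast enough for feature-by-feature scans.

Inference on a coefficient is a two-sided Wald z test, the usual convention
for ML mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LMMFit:
    """ML fit of a nested random-intercept mixed model."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    lambda_subject: float
    lambda_family: float
    loglik: float
    converged: bool

    def wald_p(self, j: int) -> float:
        """Two-sided Wald z p-value for coefficient j."""
        if self.se[j] == 0:
            return 0.0
        z = self.beta[j] / self.se[j]
        return float(2.0 * stats.norm.sf(abs(z)))


class _Structure:
    """Precomputed grouping indices for one (y, X, subject, family) problem."""

    def __init__(self, y: np.ndarray, X: np.ndarray, subject: np.ndarray,
                 family: np.ndarray | None):
        self.M = np.column_stack([X, y])  # work on [X | y] jointly
        self.n, self.k = X.shape
        _, self.subj = np.unique(subject, return_inverse=True)
        self.m_s = np.bincount(self.subj).astype(float)  # samples per subject
        if family is None:
            self.fam = None
        else:
            _, self.fam = np.unique(family, return_inverse=True)
            # family of each subject (subjects are nested in families)
            self.fam_of_subj = np.zeros(len(self.m_s), dtype=int)
            self.fam_of_subj[self.subj] = self.fam

    def quad_forms(self, lam_s: float, lam_f: float) -> tuple[np.ndarray, float]:
        """M' V0^-1 M and log|V0| at the given variance ratios."""
        M, subj, m_s = self.M, self.subj, self.m_s
        d_s = 1.0 + m_s * lam_s
        c_s = lam_s / d_s  # Sherman-Morrison weight per subject
        S = np.zeros((len(m_s), M.shape[1]))
        np.add.at(S, subj, M)
        AinvM = M - (c_s[subj, None] * S[subj])
        Q = M.T @ AinvM
        logdet = float(np.log(d_s).sum())
        if self.fam is not None and lam_f > 0.0:
            # second Sherman-Morrison step: family-level ones vector
            # u = A^-1 1 has value 1/d_s on each row of subject s
            u_row = 1.0 / d_s[subj]
            t_g = np.bincount(self.fam_of_subj, weights=m_s / d_s)
            denom = 1.0 + lam_f * t_g
            G = np.zeros((len(t_g), M.shape[1]))
            np.add.at(G, self.fam, M * u_row[:, None])
            Q = Q - (G * (lam_f / denom)[:, None]).T @ G
            logdet += float(np.log(denom).sum())
        return Q, logdet

    def neg2ll(self, lam_s: float, lam_f: float):
        """-2 log profile likelihood plus the profiled beta/cov/sigma2."""
        Q, logdet = self.quad_forms(lam_s, lam_f)
        k, n = self.k, self.n
        Qxx, Qxy, Qyy = Q[:k, :k], Q[:k, k], Q[k, k]
        xtx_inv = np.linalg.pinv(Qxx)
        beta = xtx_inv @ Qxy
        rss = float(Qyy - Qxy @ beta)
        sigma2 = max(rss / n, 1e-300)
        val = n * np.log(sigma2) + logdet + n * (1.0 + _LOG_2PI)
        return val, beta, xtx_inv, sigma2


def fit_lmm_ml(
    y: np.ndarray,
    X: np.ndarray,
    subject: np.ndarray,
    family: np.ndarray | None = None,
) -> LMMFit:
    """Fit the nested random-intercept model by maximum likelihood.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (no missing values).
    subject
        Per-row subject labels (random intercept).
    family
        Optional per-row family labels; adds a family random intercept
        above the subject one.  Subjects must be nested in families.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    struct = _Structure(y, X, np.asarray(subject),
                        None if family is None else np.asarray(family))
    two = family is not None

    def obj(theta: np.ndarray) -> float:
        lam_s = float(np.exp(theta[0]))
        lam_f = float(np.exp(theta[1])) if two else 0.0
        return struct.neg2ll(lam_s, lam_f)[0]

    x0 = np.full(2 if two else 1, np.log(0.5))
    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600},
    )
    lam_s = float(np.exp(res.x[0]))
    lam_f = float(np.exp(res.x[1])) if two else 0.0
    # the boundary (no random effect) is inaccessible on the log scale;
    # take it when it fits at least as well
    n2_opt, beta, xtx_inv, sigma2 = struct.neg2ll(lam_s, lam_f)
    n2_zero, beta0, xtx_inv0, sigma20 = struct.neg2ll(0.0, 0.0)
    if n2_zero <= n2_opt + 1e-10:
        lam_s = lam_f = 0.0
        n2_opt, beta, xtx_inv, sigma2 = n2_zero, beta0, xtx_inv0, sigma20
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, np.inf))
    return LMMFit(
        beta=beta,
        se=se,
        sigma2=sigma2,
        lambda_subject=lam_s,
        lambda_family=lam_f,
        loglik=-0.5 * n2_opt,
        converged=bool(res.success),
    )
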