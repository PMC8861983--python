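"""Small-sample inference for the REML migration model.

Implements the Kenward-Roger adjustment: an inflated covariance of the
fixed-effect estimates that accounts for the uncertainty of the estimated
within-subject covariance, together with a scaled F statistic and an
approximate denominator degrees-of-freedom.  In balanced complete designs
the adjusted test collapses onto the exact classical result: the pooled
two-sample t (F = t^2, df = n1 + n2 - 2) for a single response, and the
two-sample Hotelling T^2 F transform for a complete multivariate response —
properties that the test suite checks numerically.

All derivative computations run in the *element* parameterization of the
covariance structure (the covariance entries themselves), in which the
unstructured and diagonal structures are linear — so the second-derivative
term of the adjustment vanishes — while the separable Kronecker structure
keeps its bilinear cross terms.  The covariance of the covariance-parameter
estimates is taken as the inverse expected REML information.

A Satterthwaite approximation is provided as a cross-check and cheap
fallback for scalar contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KrWorkspace", "KrTest", "kenward_roger_test", "kr_contrast_ci",
           "satterthwaite_df"]


@dataclass(frozen=True)
class KrTest:
    """Result of a Kenward-Roger adjusted F-test."""

    F: float
    num_df: int
    denom_df: float
    p: float
    scale: float

    def __str__(self) -> str:
        return (
            f"F({self.num_df}, {self.denom_df:.2f}) = {self.F:.4f}, "
            f"p = {self.p:.4g}"
        )


class KrWorkspace:
    """Per-fit cache of the KR building blocks.

    Notation (sums run over subjects i and covariance elements j, k):

    * ``P[j]  = sum_i X_i' S_i^-1 dS_j S_i^-1 X_i``
    * ``Q[jk] = sum_i X_i' S_i^-1 dS_j S_i^-1 dS_k S_i^-1 X_i``
    * ``R[jk] = sum_i X_i' S_i^-1 d2S_jk S_i^-1 X_i`` (Kronecker cross terms)
    * ``W``   = inverse expected REML information of the elements
    * ``phi_adj = Phi + 2 Phi {sum_jk W_jk (Q_jk - P_j Phi P_k - R_jk/4)} Phi``
    """

    def __init__(self, fit):
        self.fit = fit
        V = fit.V
        basis, second = fit.structure.element_basis(fit.theta)
        self.n_par = m = len(basis)
        p = len(fit.beta)
        Phi = fit.vcov

        P = np.zeros((m, p, p))
        Q = np.zeros((m, m, p, p))
        T1 = np.zeros((m, m))          # sum_i tr(S^-1 dS_j S^-1 dS_k)
        R: dict[tuple[int, int], np.ndarray] = {}
        for pat in fit.patterns:
            ix = np.ix_(pat.cells, pat.cells)
            S = V[ix]
            Sinv = np.linalg.inv(S)
            n_i = len(pat.subjects)
            dS = np.stack([B[ix] for B in basis])            # (m, c, c)
            # Gram tensor over subjects: G[a,b,p,q] = sum_i X_i[a,p] X_i[b,q]
            G = np.einsum("nap,nbq->abpq", pat.X, pat.X)
            B_ = np.matmul(np.matmul(Sinv, dS), Sinv)        # S^-1 dS_j S^-1
            P += np.einsum("jab,abpq->jpq", B_, G)
            C = np.einsum("jba,bc,kcd->jkad", B_, S, B_)     # B_j' S B_k
            Q += np.einsum("jkab,abpq->jkpq", C, G, optimize=True)
            SD = np.matmul(Sinv, dS)                         # S^-1 dS_j
            T1 += n_i * np.einsum("jab,kba->jk", SD, SD)
            for (j, k), B2 in second.items():
                if k < j:
                    continue  # symmetric pair handled with factor 2 below
                d2 = Sinv @ B2[ix] @ Sinv
                R[(j, k)] = R.get((j, k), 0.0) + np.einsum(
                    "ab,abpq->pq", d2, G
                )

        # expected REML information over elements
        PhiP = np.matmul(Phi, P)                     # (m, p, p)
        CQ = np.einsum("pq,jkqp->jk", Phi, Q)
        CPCP = np.einsum("jpr,krp->jk", PhiP, PhiP)
        info = 0.5 * (T1 - 2.0 * CQ + CPCP)
        self.W = np.linalg.pinv(0.5 * (info + info.T))

        mid = np.einsum("jk,jkpq->pq", self.W, Q)
        mid -= np.einsum("jk,jpr,krq->pq", self.W, P, PhiP)
        for (j, k), M in R.items():
            mid -= 0.5 * self.W[j, k] * M            # 2 * (1/4): (j,k) and (k,j)
        Lam = Phi @ mid @ Phi
        self.phi = Phi
        self.phi_adj = Phi + 2.0 * Lam
        self.P = P


def kenward_roger_test(fit, L: np.ndarray) -> KrTest:
    """KR-adjusted F-test of the hypothesis L beta = 0 (L is q x p)."""
    ws = fit._kr()
    L = np.atleast_2d(np.asarray(L, float))
    q = np.linalg.matrix_rank(L)
    if q < L.shape[0]:
        raise ValueError(
            "contrast matrix is rank deficient; rows are linearly dependent"
        )
    Phi, PhiA, P, W = ws.phi, ws.phi_adj, ws.P, ws.W

    Theta = L.T @ np.linalg.solve(L @ Phi @ L.T, L)
    m = ws.n_par
    TP = np.einsum("pq,jqr->jpr", Theta @ Phi, np.einsum("jpq,qr->jpr", P, Phi))
    tr1 = np.trace(TP, axis1=1, axis2=2)
    A1 = float(tr1 @ W @ tr1)
    A2 = float(np.einsum("jk,jpq,kqp->", W, TP, TP))

    B = (A1 + 6.0 * A2) / (2.0 * q)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2) if A2 > 1e-300 else 0.0
    c1 = g / (3.0 * q + 2.0 * (1.0 - g))
    c2 = (q - g) / (3.0 * q + 2.0 * (1.0 - g))
    c3 = (q + 2.0 - g) / (3.0 * q + 2.0 * (1.0 - g))
    Estar = 1.0 / (1.0 - A2 / q) if A2 / q < 1.0 else 1.0
    Vstar = (2.0 / q) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2 * (1.0 - c3 * B))
    rho = Vstar / (2.0 * Estar**2)
    denom = q * rho - 1.0
    if denom <= 1e-12:
        df2 = np.inf
    else:
        df2 = 4.0 + (q + 2.0) / denom
    lam = df2 / (Estar * (df2 - 2.0)) if np.isfinite(df2) and df2 > 2 else 1.0 / Estar

    b = fit.beta
    Fstat = float(
        lam * (L @ b) @ np.linalg.solve(L @ PhiA @ L.T, L @ b) / q
    )
    Fstat = max(Fstat, 0.0)
    p = float(stats.f.sf(Fstat, q, df2)) if np.isfinite(df2) else float(
        stats.chi2.sf(Fstat * q, q)
    )
    return KrTest(Fstat, int(q), float(df2), p, float(lam))


def kr_contrast_ci(fit, l: np.ndarray, level: float = 0.95):
    """Scalar contrast estimate with KR standard error, df and CI."""
    l = np.asarray(l, float).ravel()
    test = kenward_roger_test(fit, l[None, :])
    ws = fit._kr()
    est = float(l @ fit.beta)
    se = float(np.sqrt(l @ ws.phi_adj @ l / test.scale))
    df = test.denom_df
    tq = stats.t.ppf(0.5 + level / 2.0, df if np.isfinite(df) else 1e9)
    return est, se, df, est - tq * se, est + tq * se


def satterthwaite_df(fit, l: np.ndarray) -> float:
    """Satterthwaite denominator df for a scalar contrast.

    df = 2 (l' Phi l)^2 / Var(l' Phi l), with the variance propagated
    through the covariance-element estimates via the delta method.
    """
    ws = fit._kr()
    l = np.asarray(l, float).ravel()
    v = float(l @ ws.phi @ l)
    grad = np.einsum("p,jpq,q->j", l @ ws.phi, ws.P, ws.phi @ l)
    denom = float(grad @ ws.W @ grad)
    if denom <= 1e-300:
        return np.inf
    return 2.0 * v**2 / denom
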