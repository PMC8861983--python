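"""Within-subject covariance structures over axis-by-time cells.

The migration response of one subject is a vector over the grid of
(visit, axis) cells — up to 3 visits x 6 axes = 18 cells.  The marginal
linear mixed model places all within-subject correlation in a structured
residual covariance V over this grid:

``unstructured``
    a free symmetric positive-definite matrix over all observed cells;
``kronecker_un``
    a separable (doubly repeated-measures) structure V = T (x) A with an
    unstructured visit factor T and an unstructured axis factor A,
    identified by fixing T[0, 0] = 1;
``diagonal``
    independent cells with a free variance per cell.

All structures are parameterized for unconstrained optimization through a
log-Cholesky map (diagonal of the Cholesky factor on the log scale), which
keeps every iterate positive definite.  For small-sample inference the same
structures also expose their *element* parameterization (the covariance
entries themselves), in which the unstructured and diagonal V are linear and
the Kronecker V is bilinear.
"""

from __future__ import annotations

import numpy as np

__all__ = ["get_structure", "Unstructured", "KroneckerUN", "Diagonal"]


def _tril_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n)


def _chol_from_free(theta: np.ndarray, n: int) -> np.ndarray:
    """Lower-triangular factor from free parameters (log-diagonal)."""
    L = np.zeros((n, n))
    L[np.tril_indices(n)] = theta
    d = np.diag_indices(n)
    L[d] = np.exp(L[d])
    return L


def _free_from_chol(L: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    M = L.copy()
    d = np.diag_indices(n)
    M[d] = np.log(np.clip(M[d], 1e-10, None))
    return M[np.tril_indices(n)]


def _dchol(theta: np.ndarray, n: int) -> list[np.ndarray]:
    """Derivatives of the Cholesky factor w.r.t. each free parameter."""
    L = _chol_from_free(theta, n)
    out = []
    rows, cols = np.tril_indices(n)
    for r, c in zip(rows, cols):
        D = np.zeros((n, n))
        D[r, c] = L[r, c] if r == c else 1.0  # chain rule through exp on diag
        out.append(D)
    return out


def nearest_pd(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped symmetric PD projection of a moment estimate."""
    S = 0.5 * (S + S.T)
    w, Q = np.linalg.eigh(S)
    w = np.clip(w, floor * max(w.max(), 1.0), None)
    return (Q * w) @ Q.T


def _sym_basis(n: int, i: int, j: int) -> np.ndarray:
    E = np.zeros((n, n))
    E[i, j] = 1.0
    E[j, i] = 1.0
    return E


class Unstructured:
    """Fully unstructured covariance over the cell grid."""

    name = "unstructured"

    def __init__(self, n_cells: int):
        self.n_cells = n_cells
        self.n_free = n_cells * (n_cells + 1) // 2

    def start(self, S: np.ndarray) -> np.ndarray:
        return _free_from_chol(np.linalg.cholesky(nearest_pd(S)))

    def build(self, theta: np.ndarray) -> np.ndarray:
        L = _chol_from_free(theta, self.n_cells)
        return L @ L.T

    def build_with_grad(
        self, theta: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        n = self.n_cells
        L = _chol_from_free(theta, n)
        V = L @ L.T
        grads = []
        for D in _dchol(theta, n):
            G = D @ L.T
            grads.append(G + G.T)
        return V, grads

    def element_basis(self, theta: np.ndarray):
        """Element-parameterization first derivatives (linear: no 2nd order)."""
        n = self.n_cells
        basis = [
            _sym_basis(n, i, j) for i, j in zip(*np.tril_indices(n))
        ]
        return basis, {}


class Diagonal:
    """Independent cells, one free variance per cell."""

    name = "diagonal"

    def __init__(self, n_cells: int):
        self.n_cells = n_cells
        self.n_free = n_cells

    def start(self, S: np.ndarray) -> np.ndarray:
        return 0.5 * np.log(np.clip(np.diag(S), 1e-10, None))

    def build(self, theta: np.ndarray) -> np.ndarray:
        return np.diag(np.exp(2.0 * theta))

    def build_with_grad(self, theta: np.ndarray):
        v = np.exp(2.0 * theta)
        V = np.diag(v)
        grads = [np.diag(2.0 * v * (np.arange(self.n_cells) == k)) for k in range(self.n_cells)]
        return V, grads

    def element_basis(self, theta: np.ndarray):
        n = self.n_cells
        basis = []
        for k in range(n):
            E = np.zeros((n, n))
            E[k, k] = 1.0
            basis.append(E)
        return basis, {}


class KroneckerUN:
    """Separable V = T (x) A: unstructured visit factor T (T[0,0] = 1 for
    identifiability) times an unstructured axis factor A.

    Cells are ordered visit-major: cell (visit v, axis a) has index
    ``v * n_axis + a``, matching the Kronecker ordering.
    """

    name = "kronecker_un"

    def __init__(self, n_time: int, n_axis: int):
        self.n_time = n_time
        self.n_axis = n_axis
        self.n_cells = n_time * n_axis
        self._nt_free = n_time * (n_time + 1) // 2  # L_T incl. fixed corner
        self._na_free = n_axis * (n_axis + 1) // 2
        # the (0,0) entry of L_T is pinned to 1, so it is not a free param
        self.n_free = (self._nt_free - 1) + self._na_free

    # -- free parameterization ------------------------------------------
    def _split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tt = np.concatenate([[0.0], theta[: self._nt_free - 1]])
        aa = theta[self._nt_free - 1:]
        return tt, aa

    def _lt(self, tt: np.ndarray) -> np.ndarray:
        """Visit Cholesky factor with L[0,0] fixed at 1."""
        L = np.zeros((self.n_time, self.n_time))
        L[np.tril_indices(self.n_time)] = tt
        d = np.diag_indices(self.n_time)
        L[d] = np.exp(L[d])
        L[0, 0] = 1.0
        return L

    def factors(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tt, aa = self._split(theta)
        LT = self._lt(tt)
        LA = _chol_from_free(aa, self.n_axis)
        return LT @ LT.T, LA @ LA.T

    def start(self, S: np.ndarray) -> np.ndarray:
        nt, na = self.n_time, self.n_axis
        S = nearest_pd(S)
        blocks = S.reshape(nt, na, nt, na).transpose(0, 2, 1, 3)
        A = blocks[range(nt), range(nt)].mean(axis=0)
        A = nearest_pd(A)
        Ainv = np.linalg.inv(A)
        T = np.einsum("stij,ji->st", blocks, Ainv) / na
        T = nearest_pd(T)
        A = A * T[0, 0]
        T = T / T[0, 0]
        LT = np.linalg.cholesky(T)
        tt = _free_from_chol(LT)
        return np.concatenate([tt[1:], _free_from_chol(np.linalg.cholesky(A))])

    def build(self, theta: np.ndarray) -> np.ndarray:
        T, A = self.factors(theta)
        return np.kron(T, A)

    def build_with_grad(self, theta: np.ndarray):
        tt, aa = self._split(theta)
        LT = self._lt(tt)
        LA = _chol_from_free(aa, self.n_axis)
        T = LT @ LT.T
        A = LA @ LA.T
        V = np.kron(T, A)
        grads = []
        rows, cols = np.tril_indices(self.n_time)
        for k, (r, c) in enumerate(zip(rows, cols)):
            if k == 0:
                continue  # fixed corner
            D = np.zeros((self.n_time, self.n_time))
            D[r, c] = LT[r, c] if r == c else 1.0
            G = D @ LT.T
            grads.append(np.kron(G + G.T, A))
        rows, cols = np.tril_indices(self.n_axis)
        for r, c in zip(rows, cols):
            D = np.zeros((self.n_axis, self.n_axis))
            D[r, c] = LA[r, c] if r == c else 1.0
            G = D @ LA.T
            grads.append(np.kron(T, G + G.T))
        return V, grads

    def element_basis(self, theta: np.ndarray):
        """Elements of T (except the fixed T[0,0]) and of A.

        V is bilinear in (T, A): the cross second derivatives
        d2V / dT_ij dA_kl = E_ij (x) F_kl are the only non-zero ones.
        """
        T, A = self.factors(theta)
        t_idx = [
            (i, j)
            for i, j in zip(*np.tril_indices(self.n_time))
            if not (i == 0 and j == 0)
        ]
        a_idx = list(zip(*np.tril_indices(self.n_axis)))
        basis = [np.kron(_sym_basis(self.n_time, i, j), A) for i, j in t_idx]
        basis += [np.kron(T, _sym_basis(self.n_axis, i, j)) for i, j in a_idx]
        second: dict[tuple[int, int], np.ndarray] = {}
        nt = len(t_idx)
        for p, (i, j) in enumerate(t_idx):
            Et = _sym_basis(self.n_time, i, j)
            for q, (k, l) in enumerate(a_idx):
                M = np.kron(Et, _sym_basis(self.n_axis, k, l))
                second[(p, nt + q)] = M
                second[(nt + q, p)] = M
        return basis, second


def get_structure(name: str, n_time: int, n_axis: int):
    """Factory: covariance structure over an ``n_time x n_axis`` cell grid."""
    n_cells = n_time * n_axis
    if name in ("unstructured", "full_un", "un"):
        return Unstructured(n_cells)
    if name in ("kronecker_un", "kronecker", "un@un"):
        return KroneckerUN(n_time, n_axis)
    if name == "diagonal":
        return Diagonal(n_cells)
    raise ValueError(f"unknown covariance structure {name!r}")
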