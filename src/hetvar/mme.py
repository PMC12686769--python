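"""Sparse mixed-model equations and REML likelihood evaluation.

The restricted log-likelihood of an animal model is evaluated through
Henderson's mixed-model equations.  For

    y = X b + Z u + e,   u ~ N(0, Sigma_u),   e ~ N(0, R),   R diagonal,

the identity

    -2 l_R = log|R| + log|Sigma_u| + log|C| + y' P y + (n - p) log 2 pi

holds, with C the unscaled MME coefficient matrix and
y'Py = y'R^-1 y - rhs' C^-1 rhs.  The fixed-effect block is small but
dense-ish (an age covariate couples every animal), so C is factorised by
block elimination: a sparse LU of the random-effect block S (pedigree
sparsity, fill-reducing symmetric ordering) plus a dense p x p Schur
complement, giving log|C| = log|S| + log|Schur|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

__all__ = ["MMESystem", "MMESolution", "numeric_hessian"]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MMESolution:
    """One REML evaluation: likelihood, solutions and reusable factors."""

    loglik: float
    b: np.ndarray
    u: np.ndarray
    yPy: float
    logdet_C: float
    lu: object            # SuperLU factor of the random block S
    Y: np.ndarray         # S^-1 B' (q x p)
    schur: np.ndarray     # p x p fixed-effect Schur complement
    sigma2_e: float
    S: sparse.spmatrix = None

    @property
    def solution(self) -> np.ndarray:
        return np.concatenate([self.b, self.u])


class MMESystem:
    """Precomputed cross-products for repeated REML evaluations.

    Weights ``w`` define per-observation residual variances sigma2_e/w_i
    and are fixed for the lifetime of the instance; only the scalar
    variance parameters change between evaluations.
    """

    def __init__(self, X: sparse.spmatrix, Z: sparse.spmatrix, y: np.ndarray,
                 weights: np.ndarray | None = None):
        self.X = sparse.csr_matrix(X)
        self.Z = sparse.csr_matrix(Z)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.w = np.ones(self.n) if weights is None else np.asarray(weights, dtype=float)
        if np.any(self.w <= 0):
            raise ValueError("weights must be positive")
        Wd = sparse.diags(self.w)
        self.XtWX = np.asarray((self.X.T @ Wd @ self.X).todense())
        self.XtWZ = np.asarray((self.X.T @ Wd @ self.Z).todense())  # p x q
        self.ZtWZ = (self.Z.T @ Wd @ self.Z).tocsc()
        self.XtWy = self.X.T @ (self.w * self.y)
        self.ZtWy = self.Z.T @ (self.w * self.y)
        self.ytWy = float(self.y @ (self.w * self.y))
        self.sum_log_w = float(np.sum(np.log(self.w)))

    def solve(self, sigma2_e: float, prior_precision: sparse.spmatrix,
              logdet_prior_cov: float) -> MMESolution:
        """REML log-likelihood at residual scale sigma2_e and the given
        random-effect prior precision (e.g. A^-1 / sigma2_a)."""
        S = (self.ZtWZ / sigma2_e + prior_precision).tocsc()
        lu = splu(S, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
        logdet_S = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        B = self.XtWZ / sigma2_e                    # p x q
        Y = lu.solve(B.T)                            # q x p
        schur = self.XtWX / sigma2_e - B @ Y
        sign, logdet_schur = np.linalg.slogdet(schur)
        if sign <= 0:
            raise FloatingPointError("MME not positive definite at these parameters")
        r1 = self.XtWy / sigma2_e
        r2 = self.ZtWy / sigma2_e
        u0 = lu.solve(r2)
        b = np.linalg.solve(schur, r1 - B @ u0)
        u = u0 - Y @ b
        yPy = self.ytWy / sigma2_e - float(r1 @ b + r2 @ u)
        logdet_R = self.n * np.log(sigma2_e) - self.sum_log_w
        m2ll = (logdet_R + logdet_prior_cov + logdet_S + logdet_schur + yPy
                + (self.n - self.p) * LOG2PI)
        return MMESolution(
            loglik=-0.5 * m2ll, b=b, u=u, yPy=yPy,
            logdet_C=logdet_S + logdet_schur, lu=lu, Y=Y, schur=schur,
            sigma2_e=sigma2_e, S=S,
        )

    # -- hat-matrix diagonal --------------------------------------------------

    def hat_diagonal(self, node: MMESolution, chunk: int = 1024) -> np.ndarray:
        """Leverages h_i = (w_i / sigma2_e) t_i' C^-1 t_i, t_i = (x_i, z_i).

        Uses the block factors of ``node``: with Sc the Schur complement,
        Y = S^-1 B' and d = diag(S^-1),

        t'C^-1 t = x'Sc^-1 x - 2 x' Sc^-1 Y'z + z'S^-1 z + (Y'z)' Sc^-1 (Y'z).
        """
        if self.Z.nnz != self.n:
            raise NotImplementedError("hat_diagonal assumes one animal per record")
        j = self.Z.indices  # animal code per record (single-entry CSR rows)
        if node.S is not None:
            if getattr(self, "_selinv", None) is None:
                from ._ldl import SelectedInverse

                self._selinv = SelectedInverse(node.S)
            d = self._selinv.diag_inv(node.S)
        else:
            d = self.diag_Sinv(node.lu, chunk=chunk)
        schur_inv = np.linalg.inv(node.schur)
        M = node.Y @ schur_inv                        # q x p
        Q = self.X @ schur_inv                        # n x p (sparse @ dense)
        term1 = np.asarray(self.X.multiply(Q).sum(axis=1)).ravel()
        term2 = -2.0 * np.asarray(self.X.multiply(M[j]).sum(axis=1)).ravel()
        term3 = d[j] + np.einsum("ij,ij->i", node.Y[j], M[j])
        h = (self.w / node.sigma2_e) * (term1 + term2 + term3)
        return h

    def diag_Sinv(self, lu, chunk: int = 1024) -> np.ndarray:
        """Diagonal of S^-1 by chunked identity solves."""
        q = self.q
        d = np.empty(q)
        for start in range(0, q, chunk):
            stop = min(start + chunk, q)
            E = np.zeros((q, stop - start))
            E[np.arange(start, stop), np.arange(stop - start)] = 1.0
            sol = lu.solve(E)
            d[start:stop] = sol[np.arange(start, stop), np.arange(stop - start)]
        return d


def numeric_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x0 (small dimension)."""
    x0 = np.asarray(x0, dtype=float)
    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1e-8)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H
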