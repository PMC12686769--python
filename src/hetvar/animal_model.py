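"""Homoscedastic animal model (REML).

The classical additive-genetic linear mixed model for a single trait:

    y = X b + Z a + e,   a ~ N(0, A sigma2_a),   e ~ N(0, W^-1 sigma2_e)

with A the pedigree numerator relationship matrix.  ``AnimalModel.fit``
maximises the restricted likelihood over (sigma2_a, sigma2_e); standard
errors come from the observed information (numeric Hessian of the REML
log-likelihood), and heritability h2 = sigma2_a / (sigma2_a + sigma2_e)
with a delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .data import DesignBundle
from .mme import MMESystem, numeric_hessian
from .pedigree import Pedigree, build_A_inverse, inbreeding

__all__ = ["AnimalModel", "AnimalModelResults", "VarianceComponents", "h2_point", "logdet_A"]


def logdet_A(ped: Pedigree, F: np.ndarray | None = None) -> float:
    """log|A| = sum of log Mendelian-sampling variances."""
    if F is None:
        F = inbreeding(ped)
    s, d = ped.sire, ped.dam
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    delta = np.ones(len(ped))
    delta[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    p = np.where(s >= 0, s, d)
    delta[one] = 0.75 - 0.25 * F[p[one]]
    return float(np.sum(np.log(delta)))


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    se: dict = field(default_factory=dict)
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    boundary: bool = False
    cov_params: np.ndarray | None = None  # covariance of (sigma2_a, sigma2_e)


def h2_point(vc: VarianceComponents) -> tuple[float, float]:
    """Heritability and delta-method SE from fitted components."""
    sa, se_ = vc.sigma2_a, vc.sigma2_e
    tot = sa + se_
    if tot <= 0:
        raise ValueError("total variance must be positive")
    h2 = sa / tot
    se_h2 = np.nan
    if vc.cov_params is not None:
        g = np.array([se_ / tot**2, -sa / tot**2])
        se_h2 = float(np.sqrt(max(g @ vc.cov_params @ g, 0.0)))
    return float(h2), se_h2


class AnimalModel:
    """Univariate animal model built from a design bundle and a pedigree.

    Parameters
    ----------
    design : DesignBundle
        Response, fixed incidence (CG classes + age) and record-to-animal map.
    ped : Pedigree, optional
        Used to assemble A^-1 and log|A| if ``ainv`` is not supplied.
    """

    def __init__(self, design: DesignBundle, ped: Pedigree | None = None,
                 ainv: sparse.spmatrix | None = None, logdet_a: float | None = None):
        self.design = design
        if ainv is None:
            if ped is None:
                raise ValueError("provide either a pedigree or a precomputed A inverse")
            F = inbreeding(ped)
            ainv = build_A_inverse(ped, F)
            logdet_a = logdet_A(ped, F)
        elif logdet_a is None:
            raise ValueError("logdet_a must accompany a precomputed A inverse")
        if ainv.shape[0] != design.n_pedigree:
            raise ValueError("A inverse dimension does not match the design")
        self.ainv = sparse.csc_matrix(ainv)
        self.logdet_a = float(logdet_a)
        self.mme = MMESystem(design.X, design.Z, design.y, design.weights)

    # -- restricted likelihood ------------------------------------------------

    def loglik(self, sigma2_a: float, sigma2_e: float):
        """REML log-likelihood (and MME solution) at the given components."""
        q = self.mme.q
        prior_prec = self.ainv / sigma2_a
        logdet_prior = q * np.log(sigma2_a) + self.logdet_a
        return self.mme.solve(sigma2_e, prior_prec, logdet_prior)

    def _start(self) -> tuple[float, float]:
        """OLS residual variance split 30/70 between genetic and residual."""
        X, y = self.mme.X, self.mme.y
        if self.mme.p <= 3000:
            beta, *_ = np.linalg.lstsq(X.toarray(), y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y - y.mean()
        v = max(float(np.var(resid)), 1e-8)
        return 0.3 * v, 0.7 * v

    def fit(self, init: tuple[float, float] | None = None, tol: float = 1e-8,
            max_iter: int = 400, method: str = "nm") -> "AnimalModelResults":
        """Maximise the restricted likelihood.

        ``method='nm'`` (default) runs a Nelder-Mead search on the log
        variances; ``method='em'`` runs classical EM-REML iterations
        (dense, for small systems; its likelihood path is monotone).
        """
        sa0, se0 = init if init is not None else self._start()
        if method == "em":
            return self._fit_em(sa0, se0, tol, max_iter)

        def negll(x):
            sa, se_ = np.exp(x)
            try:
                return -self.loglik(sa, se_).loglik
            except (RuntimeError, FloatingPointError):
                return np.inf

        res = optimize.minimize(
            negll, np.log([sa0, se0]), method="Nelder-Mead",
            options=dict(xatol=tol ** 0.5 * 10, fatol=1e-10, maxiter=max_iter),
        )
        sa, se_ = np.exp(res.x)
        return self._package(sa, se_, n_iter=res.nit, converged=bool(res.success))

    def _fit_em(self, sa, se_, tol, max_iter):
        """EM-REML with dense posterior covariance (small systems only)."""
        n, p, q = self.mme.n, self.mme.p, self.mme.q
        if p + q > 4000:
            raise ValueError("EM-REML path is dense; use method='nm' for large systems")
        T = sparse.hstack([self.mme.X, self.mme.Z]).tocsr()
        w = self.mme.w
        y = self.mme.y
        A = self.ainv.toarray()
        n_it = 0
        converged = False
        ll_trace = []
        for n_it in range(1, max_iter + 1):
            solnode = self.loglik(sa, se_)
            ll_trace.append(solnode.loglik)
            C = np.asarray(
                sparse.bmat(
                    [
                        [self.mme.XtWX / se_, self.mme.XtWZ / se_],
                        [self.mme.XtWZ.T / se_, self.mme.ZtWZ / se_ + A / sa],
                    ]
                ).todense()
            )
            Cinv = np.linalg.inv(C)
            sol = solnode.solution
            u = sol[p:]
            resid = y - T @ sol
            Cuu = Cinv[p:, p:]
            sa_new = (u @ A @ u + np.sum(A * Cuu)) / q
            # tr(W T Cinv T') via row-wise quadratic forms
            Td = T.toarray()
            tr_term = float(np.einsum("ij,jk,ik->", Td * w[:, None], Cinv, Td))
            se_new = (resid @ (w * resid) + tr_term) / n
            rel = max(abs(sa_new - sa) / max(sa, 1e-12), abs(se_new - se_) / max(se_, 1e-12))
            sa, se_ = float(max(sa_new, 1e-12)), float(max(se_new, 1e-12))
            if rel < tol:
                converged = True
                break
        out = self._package(sa, se_, n_iter=n_it, converged=converged)
        out.em_loglik_trace = ll_trace
        return out

    def _package(self, sa, se_, n_iter, converged):
        node = self.loglik(sa, se_)
        tot = sa + se_
        boundary = sa < 1e-6 * tot

        def ll_nat(x):
            return self.loglik(max(x[0], 1e-12), max(x[1], 1e-12)).loglik

        cov = None
        se_dict = {}
        try:
            H = numeric_hessian(ll_nat, np.array([sa, se_]))
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            if np.all(d > 0):
                se_dict = {"sigma2_a": float(np.sqrt(d[0])), "sigma2_e": float(np.sqrt(d[1]))}
            else:
                cov = None
        except np.linalg.LinAlgError:
            pass
        vc = VarianceComponents(
            sigma2_a=float(sa), sigma2_e=float(se_), se=se_dict, loglik=node.loglik,
            n_iter=n_iter, converged=converged, boundary=boundary, cov_params=cov,
        )
        return AnimalModelResults(self, vc, node)


class AnimalModelResults:
    """REML estimates, their uncertainty, and the BLUE/BLUP solutions."""

    def __init__(self, model: AnimalModel, vc: VarianceComponents, node):
        self.model = model
        self.vc = vc
        p = model.mme.p
        self.fe = node.solution[:p]
        self.blup = node.solution[p:]
        self.loglik = node.loglik
        self._node = node

    @property
    def sigma2_a(self):
        return self.vc.sigma2_a

    @property
    def sigma2_e(self):
        return self.vc.sigma2_e

    @property
    def h2(self):
        return h2_point(self.vc)[0]

    @property
    def h2_se(self):
        return h2_point(self.vc)[1]

    def fittedvalues(self, include_random: bool = True) -> np.ndarray:
        d = self.model.design
        out = d.X @ self.fe
        if include_random:
            out = out + self.blup[d.animal_index]
        return out

    def resid(self) -> np.ndarray:
        return self.model.design.y - self.fittedvalues()

    def summary(self) -> str:
        vc = self.vc
        h2, h2se = h2_point(vc)
        lines = [
            "Homoscedastic animal model (REML)",
            "=" * 46,
            f"records            {self.model.mme.n}",
            f"animals in A       {self.model.mme.q}",
            f"sigma2_a           {vc.sigma2_a:.6g}  (SE {vc.se.get('sigma2_a', float('nan')):.3g})",
            f"sigma2_e           {vc.sigma2_e:.6g}  (SE {vc.se.get('sigma2_e', float('nan')):.3g})",
            f"h2                 {h2:.4f}  (SE {h2se:.3g})",
            f"REML logL          {self.loglik:.4f}",
            f"iterations         {vc.n_iter}   converged: {vc.converged}"
            + ("   [boundary]" if vc.boundary else ""),
        ]
        return "\n".join(lines)

    def to_text(self) -> str:
        vc = self.vc
        h2, h2se = h2_point(vc)
        rows = {
            "model": "M1",
            "sigma2_a": vc.sigma2_a,
            "sigma2_e": vc.sigma2_e,
            "se_sigma2_a": vc.se.get("sigma2_a", ""),
            "se_sigma2_e": vc.se.get("sigma2_e", ""),
            "h2": h2,
            "se_h2": h2se,
            "loglik": vc.loglik,
            "converged": vc.converged,
        }
        return "\n".join(f"{k}\t{v}" for k, v in rows.items()) + "\n"
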