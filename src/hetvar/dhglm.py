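"""Iterative double hierarchical GLM (DHGLM) for mean and residual variance.

The trait y and a linearised response for its log residual variance are
fitted jointly as a bivariate animal model.  Given predicted
per-observation residual variances s2_i, leverages h_i (hat-matrix
diagonal of the mean part) and residuals e_i, the variance-part working
response is

    psi_i = log s2_i + (e_i^2 / (1 - h_i) - s2_i) / s2_i,

a first-order linearisation of log e_i^2 around log s2_i; it is unbiased
for the true log variance to first order whatever s2_i, which is what
makes the iteration stable.  The bivariate model uses residual weights
W = diag(1/s2_i) for the trait and Wv = diag((1-h_i)/2) for psi — each
squared residual carries about two variance units on the log scale — so
both scaling residual variances are expected to converge to ~1.

Estimation interleaves, until the components stabilise:
  1. rebuild psi and the weights from the current working state;
  2. solve the stacked mixed-model equations and apply one EM-REML
     update to G = Cov(a, a_v) and the two scaling variances, with the
     exact conditional-covariance trace terms taken from a Takahashi
     selected inverse of the sparse random-effect block;
  3. refresh the predicted residual variances (from the variance-part
     linear predictor including its breeding values), the residuals and
     the mean-part leverages.

EM steps are monotone on each working likelihood and keep G positive
semi-definite by construction, which matters because the variance-part
genetic variance is often close to its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._ldl import SelectedInverse
from .animal_model import AnimalModel, logdet_A
from .data import DesignBundle
from .mme import MMESystem, numeric_hessian
from .pedigree import Pedigree, build_A_inverse, inbreeding

__all__ = ["DHGLM", "DHGLMResults", "BivariateComponents", "update_psi", "compute_leverage"]


@dataclass
class BivariateComponents:
    sigma2_a: float
    sigma2_av: float
    sigma_a_av: float
    scale_e: float = 1.0
    scale_ev: float = 1.0
    se: dict = field(default_factory=dict)
    converged: bool = False
    cov_params: np.ndarray | None = None  # covariance of (sigma2_a, sigma2_av, sigma_a_av)

    @property
    def G(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_a, self.sigma_a_av], [self.sigma_a_av, self.sigma2_av]]
        )

    @property
    def rmv(self) -> float:
        d = self.sigma2_a * self.sigma2_av
        return float(self.sigma_a_av / np.sqrt(d)) if d > 0 else np.nan


def update_psi(resid: np.ndarray, resid_var_hat: np.ndarray, leverage: np.ndarray) -> np.ndarray:
    """Variance-part working response (exact linearisation formula)."""
    resid_var_hat = np.asarray(resid_var_hat, dtype=float)
    leverage = np.asarray(leverage, dtype=float)
    if np.any(resid_var_hat <= 0):
        raise ValueError("predicted residual variances must be positive")
    if np.any(leverage >= 1.0):
        raise ValueError("leverage of 1 makes the correction term infinite")
    e2 = np.asarray(resid, dtype=float) ** 2
    return np.log(resid_var_hat) + (e2 / (1.0 - leverage) - resid_var_hat) / resid_var_hat


def compute_leverage(
    design: DesignBundle,
    sigma2_a: float,
    scale_e: float,
    ainv: sparse.spmatrix,
    resid_var_hat: np.ndarray | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Hat-matrix diagonal of the weighted mean-part mixed model.

    Residual variance of record i is ``scale_e * resid_var_hat_i``; the
    random animal effect has covariance ``sigma2_a * A``.  Computed
    exactly through the sparse factor of the mixed-model equations.
    """
    w = np.ones(design.n_records) if resid_var_hat is None else 1.0 / np.asarray(resid_var_hat)
    mme = MMESystem(design.X, design.Z, design.y, weights=w)
    if cache:  # reuse a previous symbolic analysis of the S pattern
        mme._selinv = cache.get("selinv")
    node = mme.solve(scale_e, ainv / sigma2_a, ainv.shape[0] * np.log(sigma2_a))
    h = mme.hat_diagonal(node)
    if cache is not None:
        cache["selinv"] = mme._selinv
    if np.any(h >= 1.0 + 1e-10):
        raise FloatingPointError("leverage >= 1; model numerically degenerate")
    return np.minimum(h, 1.0 - 1e-10)


class _BivariateMME:
    """Stacked two-trait MME (shared animal structure, G (x) A prior).

    Residual variances are scale_e / w1_i for the trait and
    scale_ev / w2_i for the working response.  Used for likelihood
    evaluations (standard errors, tests); the EM engine drives it
    through ``solve``.
    """

    def __init__(self, X, Xv, Z, y, psi, w1, w2, ainv, logdet_a):
        self.Xs = sparse.block_diag([X, Xv], format="csr")
        self.Zs = sparse.block_diag([Z, Z], format="csr")
        self.ys = np.concatenate([y, psi])
        self.w1 = np.asarray(w1, dtype=float)
        self.w2 = np.asarray(w2, dtype=float)
        self.ainv = sparse.csc_matrix(ainv)
        self.logdet_a = float(logdet_a)
        self.q = ainv.shape[0]
        self.p1 = X.shape[1]
        self.p2 = Xv.shape[1]
        self.n1 = X.shape[0]

    def prior_precision(self, G: np.ndarray):
        sign, logdet_G = np.linalg.slogdet(G)
        if sign <= 0:
            raise FloatingPointError("G not positive definite")
        Gi = np.linalg.inv(G)
        # scalar multiplication keeps the pattern even for zero entries,
        # so the selected-inverse symbolic analysis stays valid
        P = sparse.bmat(
            [[Gi[0, 0] * self.ainv, Gi[0, 1] * self.ainv],
             [Gi[0, 1] * self.ainv, Gi[1, 1] * self.ainv]],
            format="csc",
        )
        logdet_prior = self.q * logdet_G + 2.0 * self.logdet_a
        return P, logdet_prior

    def mme(self, s1: float, s2: float) -> MMESystem:
        w = np.concatenate([self.w1 / s1, self.w2 / s2])
        return MMESystem(self.Xs, self.Zs, self.ys, weights=w)

    def solve(self, G, s1, s2):
        mme = self.mme(s1, s2)
        P, logdet_prior = self.prior_precision(G)
        node = mme.solve(1.0, P, logdet_prior)
        # the stacked weights absorb the scales; restore the true
        # log-determinant of R: sum log(s/w) = -sum log(w/s)
        return mme, node

    def loglik(self, G, s1, s2) -> float:
        _, node = self.solve(G, s1, s2)
        return node.loglik


@dataclass
class DhglmState:
    psi: np.ndarray
    resid_var_hat: np.ndarray
    leverage: np.ndarray
    W: np.ndarray
    Wv: np.ndarray
    iteration: int
    rel_change: float


class DHGLM:
    """Bivariate mean/residual-variance animal model, fitted iteratively.

    Parameters
    ----------
    design : DesignBundle
        Mean-part response and incidence structures.
    ped : Pedigree, optional (or supply ``ainv`` + ``logdet_a``)
    var_part_fixed : bool
        Mirror the CG + age fixed structure in the variance part
        (otherwise an intercept only).
    """

    def __init__(self, design: DesignBundle, ped: Pedigree | None = None,
                 ainv=None, logdet_a=None, var_part_fixed: bool = True):
        self.design = design
        if ainv is None:
            if ped is None:
                raise ValueError("provide a pedigree or a precomputed A inverse")
            F = inbreeding(ped)
            ainv = build_A_inverse(ped, F)
            logdet_a = logdet_A(ped, F)
        self.ainv = sparse.csc_matrix(ainv)
        self.logdet_a = float(logdet_a)
        self.var_part_fixed = var_part_fixed
        self.Xv = (
            design.X
            if var_part_fixed
            else sparse.csr_matrix(np.ones((design.n_records, 1)))
        )
        coo = self.ainv.tocoo()
        self._a_rows = coo.row.astype(np.int64)
        self._a_cols = coo.col.astype(np.int64)
        self._a_vals = coo.data
        self._selinv2: SelectedInverse | None = None
        self._lev_cache: dict = {}

    # -- score machinery ------------------------------------------------------

    def _score_step(self, biv: _BivariateMME, G, s1, s2):
        """Exact REML log-likelihood and score on the working response.

        The gradient uses the standard mixed-model identities: with
        M = U'A^-1 U + Tr (Tr_jk = tr(A^-1 Cov(u_j, u_k)), from the
        Takahashi selected inverse plus the fixed-effect Schur correction),

            dl/dG = -1/2 (q G^-1 - G^-1 M G^-1),
            dl/ds = (T - n s) / (2 s^2),  T = sum w ehat^2 + s * sum h.
        """
        mme, node = biv.solve(G, s1, s2)
        q = biv.q
        if self._selinv2 is None:
            # symbolic analysis on a pattern-complete template (all four
            # A-inverse blocks structurally nonzero + full diagonal), valid
            # for every G encountered later
            ap = self.ainv.copy()
            ap.data = np.ones_like(ap.data)
            template = (
                sparse.bmat([[ap, ap], [ap, ap]], format="csc")
                + sparse.identity(2 * q, format="csc")
            )
            self._selinv2 = SelectedInverse(template)
        self._selinv2.factor(node.S)
        d = self._selinv2.diag_inv()
        schur_inv = np.linalg.inv(node.schur)
        U = [node.u[:q], node.u[q:]]
        Yb = [node.Y[:q], node.Y[q:]]
        AY = [self.ainv @ Yb[0], self.ainv @ Yb[1]]
        M = np.empty((2, 2))
        for j in range(2):
            for k in range(j, 2):
                s_emp = float(U[j] @ (self.ainv @ U[k]))
                t_sel = self._selinv2.pattern_sum(
                    self._a_rows + j * q, self._a_cols + k * q, self._a_vals
                )
                t_schur = float(np.einsum("ij,ji->", schur_inv, Yb[k].T @ AY[j]))
                M[j, k] = M[k, j] = s_emp + t_sel + t_schur
        Gi = np.linalg.inv(G)
        dG = -0.5 * (q * Gi - Gi @ M @ Gi)
        # leverage-type diagonal of the stacked system (sigma2_e = 1)
        fitted = mme.X @ node.b + node.u[mme.Z.indices]
        ehat = biv.ys - fitted
        Ms = node.Y @ schur_inv
        jz = mme.Z.indices
        Q = mme.X @ schur_inv
        term1 = np.asarray(mme.X.multiply(Q).sum(axis=1)).ravel()
        term2 = -2.0 * np.asarray(mme.X.multiply(Ms[jz]).sum(axis=1)).ravel()
        term3 = d[jz] + np.einsum("ij,ij->i", node.Y[jz], Ms[jz])
        h_stack = mme.w * (term1 + term2 + term3)
        n1 = biv.n1
        w_stack = mme.w
        T1 = float(w_stack[:n1] @ ehat[:n1] ** 2 + h_stack[:n1].sum()) * s1
        T2 = float(w_stack[n1:] @ ehat[n1:] ** 2 + h_stack[n1:].sum()) * s2
        n2 = len(ehat) - n1
        ds1 = (T1 - n1 * s1) / (2 * s1**2)
        ds2 = (T2 - n2 * s2) / (2 * s2**2)
        return node.loglik, dG, ds1, ds2, (node.b, node.u), M

    @staticmethod
    def _theta_to_G(theta):
        ea, eb = np.exp(theta[0]), np.exp(theta[1])
        r = np.tanh(theta[2])
        c = r * np.sqrt(ea * eb)
        return np.array([[ea, c], [c, eb]]), float(np.exp(theta[3])), float(np.exp(theta[4]))

    def _inner_fit(self, biv, theta0, constrain, maxiter=60):
        """Maximise the working REML likelihood with analytic gradients.

        Block-coordinate scheme: the mean-part parameters (log sigma2_a,
        log scale_e) and the variance-part parameters (log sigma2_av,
        atanh r, log scale_ev) are optimised in separate L-BFGS passes.
        The variance-part block is weakly identified (a long flat ridge
        in (sigma2_av, r)); optimising everything jointly lets that ridge
        drag the well-identified mean-part variance along with it, while
        separate passes keep each block at its own conditional optimum.
        The box caps variances at e^1 and |atanh r| at 2 — near-singular
        G (|r| -> 1) makes the G-inverse prior precision explode and
        collapses the fit.
        """
        from scipy import optimize

        lob = np.array([-18.0, -18.0, -2.0, -5.0, -5.0])
        upb = np.array([1.0, 1.0, 2.0, 5.0, 5.0])
        theta = np.clip(np.asarray(theta0, dtype=float), lob, upb)
        if constrain:
            theta[1] = np.log(1e-8)
            theta[2] = 0.0

        state = {}

        def fun_grad_subset(sub, free):
            th = theta.copy()
            th[free] = sub
            th = np.clip(th, lob, upb)
            G, s1, s2 = self._theta_to_G(th)
            try:
                ll, dG, ds1, ds2, sol, _ = self._score_step(biv, G, s1, s2)
            except (FloatingPointError, RuntimeError, ValueError):
                return np.inf, np.zeros(len(free))
            state["sol"] = sol
            ea, eb, c = G[0, 0], G[1, 1], G[0, 1]
            r = np.tanh(th[2])
            g = np.empty(5)
            g[0] = dG[0, 0] * ea + 2 * dG[0, 1] * (c / 2)
            g[1] = dG[1, 1] * eb + 2 * dG[0, 1] * (c / 2)
            g[2] = 2 * dG[0, 1] * np.sqrt(ea * eb) * (1 - r**2)
            g[3] = ds1 * s1
            g[4] = ds2 * s2
            return -ll, -g[free]

        blocks = ([np.array([0, 3, 4])] if constrain
                  else [np.array([0, 3]), np.array([1, 2, 4])])
        for free in blocks:
            res = optimize.minimize(
                fun_grad_subset, theta[free], args=(free,), jac=True,
                method="L-BFGS-B", bounds=list(zip(lob[free], upb[free])),
                options=dict(maxiter=maxiter, ftol=1e-12, gtol=1e-8),
            )
            theta[free] = np.clip(res.x, lob[free], upb[free])
        if "sol" not in state:  # every evaluation failed
            raise FloatingPointError("inner REML fit failed")
        # re-evaluate at the final point so solutions match theta
        G, s1, s2 = self._theta_to_G(theta)
        ll, _, _, _, sol, _ = self._score_step(biv, G, s1, s2)
        return theta, G, s1, s2, sol, ll

    def fit(self, tol: float = 1e-6, max_outer: int = 30, compute_se: bool = True,
            constrain_var_genetic: bool = False) -> "DHGLMResults":
        """Run the interleaved EM / working-response iteration.

        ``constrain_var_genetic`` pins the variance-part genetic variance
        (and the genetic covariance) at zero, reducing the mean part to
        the homoscedastic animal model up to the working weights.
        """
        d = self.design
        n = d.n_records
        # -- initialisation from the homoscedastic fit ----------------------
        m1 = AnimalModel(d, ainv=self.ainv, logdet_a=self.logdet_a).fit()
        resid = m1.resid()
        s2_hat = np.full(n, m1.sigma2_e)
        h = compute_leverage(d, m1.sigma2_a, 1.0, self.ainv, resid_var_hat=s2_hat,
                             cache=self._lev_cache)
        G = np.array([[max(m1.sigma2_a, 1e-8), 0.0], [0.0, 1e-3]])
        theta = np.array([np.log(G[0, 0]), np.log(G[1, 1]), 0.0, 0.0, 0.0])
        s1 = s2 = 1.0
        trace = []
        prev = None
        converged = False
        rel = np.inf
        it = 0
        for it in range(1, max_outer + 1):
            psi = update_psi(resid, s2_hat, h)
            w1 = 1.0 / np.maximum(s2_hat, 1e-10)
            w2 = np.maximum((1.0 - h) / 2.0, 1e-10)
            biv = _BivariateMME(d.X, self.Xv, d.Z, d.y, psi, w1, w2,
                                self.ainv, self.logdet_a)
            # inner REML fit (analytic-gradient quasi-Newton) on this
            # fixed working response, warm-started from the previous one
            theta, G, s1, s2, (b_all, u_all), ll = self._inner_fit(
                biv, theta, constrain_var_genetic,
                maxiter=30 if it == 1 else 15,
            )
            p1 = biv.p1
            q = biv.q
            b, bv = b_all[:p1], b_all[p1:]
            a, av = u_all[:q], u_all[q:]
            # -- refresh the working state ---------------------------------
            eta_v = np.clip(self.Xv @ bv + av[d.animal_index], -30.0, 30.0)
            # damp the working-variance refresh: fixed points are unchanged
            # but explosive feedback through psi is suppressed
            s2_hat = np.exp(0.7 * eta_v + 0.3 * np.log(s2_hat))
            resid = d.y - d.X @ b - a[d.animal_index]
            h = compute_leverage(d, max(G[0, 0], 1e-10), s1, self.ainv,
                                 resid_var_hat=s2_hat, cache=self._lev_cache)
            cur = np.array([G[0, 0], G[1, 1], G[0, 1], s1, s2])
            if prev is not None:
                # near-zero components compared on an absolute 1e-6 scale
                denom = np.maximum(np.abs(prev), 1e-6)
                rel = float(np.max(np.abs(cur - prev) / denom))
                trace.append((it, *cur, rel))
                if rel < tol:
                    converged = True
                    break
            else:
                trace.append((it, *cur, np.inf))
            prev = cur

        comp = BivariateComponents(
            sigma2_a=float(G[0, 0]), sigma2_av=float(G[1, 1]), sigma_a_av=float(G[0, 1]),
            scale_e=float(s1), scale_ev=float(s2), converged=converged,
        )
        if compute_se and not constrain_var_genetic:
            self._add_se(comp, biv)
        psi = update_psi(resid, s2_hat, h)
        state = DhglmState(psi=psi, resid_var_hat=s2_hat, leverage=h,
                           W=1.0 / s2_hat, Wv=(1.0 - h) / 2.0,
                           iteration=it, rel_change=rel)
        return DHGLMResults(self, comp, state, (b, bv, a, av), ll, trace, m1)

    @staticmethod
    def _add_se(comp: BivariateComponents, biv: _BivariateMME) -> None:
        """Observed-information SEs on the natural (co)variance scale."""

        def ll_nat(x):
            sa2, sav2, c, s1, s2 = x
            G = np.array([[sa2, c], [c, sav2]])
            try:
                return biv.loglik(G, s1, s2)
            except (FloatingPointError, RuntimeError):
                return -np.inf

        x0 = np.array([comp.sigma2_a, comp.sigma2_av, comp.sigma_a_av,
                       comp.scale_e, comp.scale_ev])
        try:
            with np.errstate(all="ignore"):
                H = numeric_hessian(ll_nat, x0, rel_step=1e-3)
                cov = np.linalg.inv(-H)
            dvar = np.diag(cov)
            if np.all(np.isfinite(dvar)) and np.all(dvar[:3] > 0):
                comp.se = {
                    "sigma2_a": float(np.sqrt(dvar[0])),
                    "sigma2_av": float(np.sqrt(dvar[1])),
                    "sigma_a_av": float(np.sqrt(dvar[2])),
                    "scale_e": float(np.sqrt(max(dvar[3], 0))),
                    "scale_ev": float(np.sqrt(max(dvar[4], 0))),
                }
                comp.cov_params = cov[:3, :3]
        except np.linalg.LinAlgError:
            pass


class DHGLMResults:
    """Converged DHGLM fit: components, working state and solutions."""

    def __init__(self, model, components, state, solutions, loglik, trace, m1_results):
        self.model = model
        self.components = components
        self.state = state
        self.fe_mean, self.fe_var, self.blup_mean, self.blup_var = solutions
        self.loglik = loglik
        self.trace = trace
        self.m1 = m1_results

    @property
    def sigma2_a(self):
        return self.components.sigma2_a

    @property
    def sigma2_av(self):
        return self.components.sigma2_av

    @property
    def rmv(self):
        return self.components.rmv

    def mean_residual_variance(self) -> float:
        """Average fitted residual variance on the observation scale."""
        return float(np.mean(self.state.resid_var_hat * self.components.scale_e))

    def h2(self) -> float:
        tot = self.sigma2_a + self.mean_residual_variance()
        return self.sigma2_a / tot

    def variance_part_trace(self) -> np.ndarray:
        return np.asarray(self.trace)

    def summary(self) -> str:
        c = self.components
        lines = [
            "Double hierarchical GLM (bivariate EM-REML)",
            "=" * 48,
            f"records              {self.model.design.n_records}",
            f"sigma2_a (mean)      {c.sigma2_a:.6g}  (SE {c.se.get('sigma2_a', float('nan')):.3g})",
            f"sigma2_av (log var)  {c.sigma2_av:.6g}  (SE {c.se.get('sigma2_av', float('nan')):.3g})",
            f"sigma_a,av           {c.sigma_a_av:.6g}  (SE {c.se.get('sigma_a_av', float('nan')):.3g})",
            f"r_mv                 {c.rmv:.4f}",
            f"scale_e / scale_ev   {c.scale_e:.4f} / {c.scale_ev:.4f}",
            f"mean resid variance  {self.mean_residual_variance():.5g}",
            f"h2 (mean)            {self.h2():.4f}",
            f"outer iterations     {self.state.iteration}   converged: {c.converged}"
            f"   (last rel change {self.state.rel_change:.2e})",
        ]
        return "\n".join(lines)
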