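"""Genetically structured (exponential) residual-variance model, by MCMC.

The observation model puts genetics on both the mean and the log residual
variance:

    y_i = x_i b + a_i + exp(0.5 (x_i b* + a*_i)) eps_i,   eps_i ~ N(0,1),

with (a, a*) ~ N(0, G (x) A), G the 2x2 genetic covariance whose
correlation rho couples mean and variance.  Fixed effects have flat
priors; G has a proper but weak inverse-Wishart prior.  Sampling is by
blockwise Gibbs (b, a, G) with Metropolis steps for the variance part;
see ``_mcmc`` for the kernel.  Heritability under this model depends on
the systematic variance-part effects: h2_i = sigma2_a / (sigma2_a +
exp(x_i b* + sigma2_a*/2)), summarised per level and per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .animal_model import logdet_A
from .data import DesignBundle
from .pedigree import Pedigree, build_A_inverse, inbreeding

__all__ = [
    "GSEVM",
    "GSEVMResults",
    "ChainResult",
    "GsevmParams",
    "log_likelihood",
    "geweke_diagnostic",
    "effective_sample_size",
]


@dataclass
class GsevmParams:
    """One parameter state of the exponential variance model."""

    b: np.ndarray
    b_star: np.ndarray
    a: np.ndarray
    a_star: np.ndarray
    sigma2_a: float
    sigma2_astar: float
    rho: float


def log_likelihood(params: GsevmParams, design: DesignBundle) -> float:
    """Exact observation log-likelihood at the given parameter state."""
    d = design
    mean = d.X @ params.b + params.a[d.animal_index]
    lv = d.X @ params.b_star + params.a_star[d.animal_index]
    r = d.y - mean
    return float(-0.5 * np.sum(np.log(2 * np.pi) + lv + r**2 * np.exp(-lv)))


@dataclass
class ChainResult:
    """Thinned MCMC draws with metadata and per-parameter summaries."""

    draws: pd.DataFrame
    n_iter: int
    burn_in: int
    thin: int
    acceptance_rates: dict
    seed: int
    a_mean: np.ndarray = field(repr=False, default=None)
    astar_mean: np.ndarray = field(repr=False, default=None)

    @property
    def n_kept(self) -> int:
        return len(self.draws)

    def posterior_mean(self) -> pd.Series:
        return self.draws.mean()

    def posterior_sd(self) -> pd.Series:
        return self.draws.std(ddof=1)

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        alpha = (1 - level) / 2
        return self.draws.quantile([alpha, 1 - alpha]).T

    def geweke(self, frac_first: float = 0.1, frac_last: float = 0.5,
               alpha: float = 0.05) -> pd.DataFrame:
        return geweke_diagnostic(self.draws, frac_first, frac_last, alpha)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_iter={self.n_iter} burn_in={self.burn_in} "
                     f"thin={self.thin} seed={self.seed}\n")
            self.draws.to_csv(fh, sep="\t", index=False)


def _spectral_var_batch(x: np.ndarray, n_batches: int = 25) -> float:
    """Variance of the segment mean via batch means (spectral density at 0)."""
    n = len(x)
    nb = min(n_batches, max(n // 10, 1))
    if nb < 2:
        return float(np.var(x) / n)
    m = n // nb
    means = x[: nb * m].reshape(nb, m).mean(axis=1)
    return float(np.var(means, ddof=1) / nb)


def geweke_diagnostic(draws, frac_first: float = 0.1, frac_last: float = 0.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Stationarity z-scores comparing early and late chain segments.

    z = (m1 - m2) / sqrt(Var(m1) + Var(m2)) with segment-mean variances
    estimated by batch means (robust to autocorrelation).  A parameter
    fails at |z| > z_{1-alpha/2}; constant chains are flagged degenerate.
    """
    if isinstance(draws, (pd.Series, np.ndarray)):
        draws = pd.DataFrame({"x": np.asarray(draws)})
    zcrit = stats.norm.ppf(1 - alpha / 2)
    out = []
    for col in draws.columns:
        x = draws[col].to_numpy(dtype=float)
        n = len(x)
        x1 = x[: int(frac_first * n)]
        x2 = x[n - int(frac_last * n):]
        if np.ptp(x) == 0 or len(x1) < 10 or len(x2) < 10:
            out.append((col, np.nan, False, True))
            continue
        v1 = _spectral_var_batch(x1)
        v2 = _spectral_var_batch(x2)
        if v1 + v2 <= 0:
            out.append((col, np.nan, False, True))
            continue
        z = (x1.mean() - x2.mean()) / np.sqrt(v1 + v2)
        out.append((col, float(z), bool(abs(z) <= zcrit), False))
    return pd.DataFrame(out, columns=["parameter", "z", "passed", "degenerate"]).set_index(
        "parameter"
    )


def effective_sample_size(x: np.ndarray, max_lag: int | None = None) -> float:
    """ESS via initial-positive-sequence autocorrelation summation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    max_lag = max_lag or min(n // 3, 1000)
    acf = np.correlate(xc, xc, mode="full")[n - 1 : n + max_lag] / (np.arange(n, n - max_lag - 1, -1))
    acf = acf / acf[0]
    s = 1.0
    for k in range(1, max_lag):
        if acf[k] <= 0:
            break
        s += 2 * acf[k]
    return float(n / s)


class GSEVM:
    """Bayesian exponential variance model on a pedigree.

    Parameters
    ----------
    design : DesignBundle
        Response and shared fixed structure (used for both parts).
    ped : Pedigree, optional (or ``ainv``)
    prior_df : float
        Inverse-Wishart degrees of freedom for G (weakly informative).
    prior_scale : float
        Diagonal of the inverse-Wishart scale matrix.
    """

    def __init__(self, design: DesignBundle, ped: Pedigree | None = None,
                 ainv=None, prior_df: float = 4.0, prior_scale: float = 0.01):
        self.design = design
        if ainv is None:
            if ped is None:
                raise ValueError("provide a pedigree or a precomputed A inverse")
            ainv = build_A_inverse(ped, inbreeding(ped))
        self.ainv = sparse.csr_matrix(ainv)
        self.prior_df = float(prior_df)
        self.prior_scale = float(prior_scale)
        if self.ainv.shape[0] != design.n_pedigree:
            raise ValueError("A inverse dimension does not match design")
        # one record per animal is assumed by the kernel
        rec_of = np.full(design.n_pedigree, -1, dtype=np.int64)
        for rec, an in enumerate(design.animal_index):
            if rec_of[an] >= 0:
                raise ValueError("multiple records per animal; clean the data first")
            rec_of[an] = rec
        self._rec_of = rec_of

    def fit(self, n_iter: int = 150_000, burn_in: int = 20_000, thin: int = 10,
            seed: int = 0, init: dict | None = None, prior_only: bool = False,
            variance_part: bool = True) -> "GSEVMResults":
        """Run the sampler and summarise the chain.

        ``prior_only`` drops all data terms (prior-recovery checks);
        ``variance_part=False`` freezes a* at 0, so the residual variance
        reduces to the systematic part exp(x_i b*) — the homoscedastic
        special case when the variance-part predictors are constant.
        """
        from ._mcmc import run_sampler

        d = self.design
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        X = sparse.csr_matrix(d.X)
        XT = X.tocsc()
        init = init or {}
        # starting values: per-CG means for b, pooled log residual variance
        # for the b* intercept columns
        y = d.y
        b0 = np.asarray(init.get("b", _default_b0(d)))
        resid0 = y - X @ b0
        v0 = max(float(np.var(resid0)), 1e-6)
        bs_default = np.zeros(d.X.shape[1])
        ncg = len(d.cg_levels)
        bs_default[:ncg] = np.log(0.7 * v0)
        bs0 = np.asarray(init.get("b_star", bs_default))
        sa0 = float(init.get("sigma2_a", 0.3 * v0))
        sas0 = float(init.get("sigma2_astar", 1e-3))

        # symbolic pieces for the blocked breeding-value update
        if not hasattr(self, "_ablock"):
            from ._ldl import SelectedInverse

            si = SelectedInverse(self.ainv.tocsc())
            Sp = self.ainv.tocsc()[si.perm][:, si.perm].tocsc()
            Sp.sort_indices()
            q = self.ainv.shape[0]
            diag_pos = np.empty(q, dtype=np.int64)
            for j in range(q):
                lo, hi = Sp.indptr[j], Sp.indptr[j + 1]
                diag_pos[j] = lo + int(np.searchsorted(Sp.indices[lo:hi], j))
            self._ablock = (
                Sp.indptr.astype(np.int64), Sp.indices.astype(np.int64), Sp.data,
                diag_pos, si.perm.astype(np.int64), si.iperm.astype(np.int64),
                si.parent.astype(np.int64), si.Lp.astype(np.int64),
            )

        draws, a_mean, astar_mean, acc_as, acc_bs, scale_bs = run_sampler(
            y,
            X.indptr.astype(np.int64), X.indices.astype(np.int64), X.data,
            XT.indptr.astype(np.int64), XT.indices.astype(np.int64), XT.data,
            np.asarray(d.animal_index, dtype=np.int64),
            self._rec_of,
            self.ainv.indptr.astype(np.int64), self.ainv.indices.astype(np.int64),
            self.ainv.data,
            *self._ablock,
            self.prior_df, self.prior_scale, self.prior_scale,
            int(n_iter), int(burn_in), int(thin),
            int(seed) % 2**31,
            sa0, sas0,
            b0.astype(np.float64), bs0.astype(np.float64),
            0 if prior_only else 1,
            1 if variance_part else 0,
        )
        cols = (["sigma2_a", "sigma2_astar", "cov_a_astar", "rho"]
                + [f"b:{c}" for c in d.column_names]
                + [f"bstar:{c}" for c in d.column_names])
        frame = pd.DataFrame(draws, columns=cols)
        chain = ChainResult(
            draws=frame, n_iter=n_iter, burn_in=burn_in, thin=thin,
            acceptance_rates={
                "a_star": float(acc_as),
                "b_star_min": float(np.min(acc_bs)) if len(acc_bs) else np.nan,
                "b_star_max": float(np.max(acc_bs)) if len(acc_bs) else np.nan,
            },
            seed=seed, a_mean=a_mean, astar_mean=astar_mean,
        )
        return GSEVMResults(self, chain)


def _default_b0(d: DesignBundle) -> np.ndarray:
    b0 = np.zeros(d.X.shape[1])
    ncg = len(d.cg_levels)
    # per-CG mean of y as the starting CG effect
    Xcg = d.X[:, :ncg]
    counts = np.asarray(Xcg.sum(axis=0)).ravel()
    sums = Xcg.T @ d.y
    with np.errstate(invalid="ignore", divide="ignore"):
        b0[:ncg] = np.where(counts > 0, sums / np.maximum(counts, 1), d.y.mean())
    return b0


class GSEVMResults:
    """Posterior summaries of the exponential variance model."""

    def __init__(self, model: GSEVM, chain: ChainResult):
        self.model = model
        self.chain = chain

    # -- point estimates ------------------------------------------------------

    @property
    def sigma2_a(self) -> float:
        return float(self.chain.draws["sigma2_a"].mean())

    @property
    def sigma2_astar(self) -> float:
        return float(self.chain.draws["sigma2_astar"].mean())

    @property
    def rho(self) -> float:
        return float(self.chain.draws["rho"].mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.chain.draws[name].std(ddof=1))

    def mc_error(self, name: str) -> float:
        x = self.chain.draws[name].to_numpy()
        return float(x.std(ddof=1) / np.sqrt(effective_sample_size(x)))

    # -- derived quantities ---------------------------------------------------

    def h2_levels(self, weighted: bool = False) -> pd.Series:
        """Per-draw heritability at each record's variance-part predictor.

        h2_i = sigma2_a / (sigma2_a + exp(x_i b* + sigma2_a*/2)), averaged
        over draws then over records (unweighted mean over records by
        default, record weights optional - identical here since levels are
        per record).
        """
        d = self.model.design
        p = d.X.shape[1]
        bs = self.chain.draws.iloc[:, 4 + p : 4 + 2 * p].to_numpy()
        sa = self.chain.draws["sigma2_a"].to_numpy()
        sas = self.chain.draws["sigma2_astar"].to_numpy()
        Xb = d.X @ bs.T  # n x draws
        h2 = sa / (sa + np.exp(Xb + 0.5 * sas))
        return pd.Series(h2.mean(axis=1), name="h2")

    def h2(self) -> float:
        """Posterior-mean heritability averaged over systematic-effect levels."""
        return float(self.h2_levels().mean())

    def residual_variance_effects(self) -> dict:
        """Dispersion of posterior-mean variance-part systematic effects.

        Reported as the variance of the posterior-mean b* CG levels and
        the absolute posterior-mean age slope contribution (an
        interpretation of 'systematic effects on residual variance').
        """
        d = self.model.design
        p = d.X.shape[1]
        ncg = len(d.cg_levels)
        bs_mean = self.chain.draws.iloc[:, 4 + p : 4 + 2 * p].mean().to_numpy()
        out = {"cg_star_var": float(np.var(bs_mean[:ncg]))}
        if p > ncg:
            age = np.asarray(d.X[:, ncg].todense()).ravel()
            out["age_star_var"] = float(np.var(age * bs_mean[ncg]))
        return out

    def summary(self) -> str:
        ch = self.chain
        gw = ch.geweke()
        lines = [
            "Exponential variance model (MCMC)",
            "=" * 52,
            f"iterations {ch.n_iter}  burn-in {ch.burn_in}  thin {ch.thin}"
            f"  kept {ch.n_kept}",
            f"acceptance a* {ch.acceptance_rates['a_star']:.3f}  "
            f"b* [{ch.acceptance_rates['b_star_min']:.2f}, "
            f"{ch.acceptance_rates['b_star_max']:.2f}]",
            "",
            "parameter        post.mean    post.SD      MCSE     Geweke z",
        ]
        for name in ["sigma2_a", "sigma2_astar", "rho"]:
            x = ch.draws[name]
            z = gw.loc[name, "z"] if name in gw.index else np.nan
            lines.append(
                f"{name:<16} {x.mean():>10.5g} {x.std(ddof=1):>10.3g} "
                f"{self.mc_error(name):>10.3g} {z:>9.2f}"
            )
        lines.append(f"h2 (mean over levels)  {self.h2():.4f}")
        return "\n".join(lines)
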