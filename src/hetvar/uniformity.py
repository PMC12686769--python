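"""Uniformity (canalisation) parameters derived from fitted components.

Three quantities summarise how much of the residual variance is under
genetic control and how it is coupled to the trait mean:

* hv2 — heritability of the residual variance,
  hv2 = sigma2_av_add / (2 sigma_p^4 + 3 sigma2_av_add),
  where sigma2_av_add is the variance-part genetic variance expressed on
  the additive (trait-units^4) scale and sigma_p^4 = (sigma_p^2)^2;
* GCV_E — genetic coefficient of variation of residual variance,
  sqrt(sigma2_av_add) / mean residual variance (DHGLM convention) or the
  lognormal CV sqrt(exp(sigma2_a*) - 1) (exponential-model convention);
* r_mv — genetic correlation between mean and residual variance,
  sigma_a,av / sqrt(sigma2_a sigma2_av); in the exponential model this is
  the correlation parameter rho itself.

The log-scale variance converts to the additive scale through the
lognormal variance identity Var(exp(Xb* + a*)) = m^2 (exp(s2) - 1) with
m the mean residual variance; the familiar first-order form m^2 * s2 is
available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "additive_scale_variance",
    "hv2",
    "gcv_e",
    "rmv",
    "h2_m3_levels",
    "UniformityReport",
]


def additive_scale_variance(
    sigma2_av_log: float, mean_resid_var: float, method: str = "exact"
) -> float:
    """Variance-part genetic variance on the additive (trait-units^4) scale.

    ``exact`` uses the lognormal variance, m^2 (exp(s2) - 1); ``first_order``
    the small-variance linearisation m^2 s2.
    """
    if sigma2_av_log < 0 or mean_resid_var < 0:
        raise ValueError("variances must be non-negative")
    m2 = mean_resid_var**2
    if method == "exact":
        return float(m2 * np.expm1(sigma2_av_log))
    if method == "first_order":
        return float(m2 * sigma2_av_log)
    raise ValueError(f"unknown method {method!r}")


def hv2(
    sigma2_av_add: float,
    sigma2_p: float,
    cov_matrix: np.ndarray | None = None,
) -> tuple[float, float]:
    """Heritability of residual variance, with optional delta-method SE.

    ``cov_matrix`` is the 2x2 covariance of (sigma2_av_add, sigma2_p);
    without it the SE is returned as NaN.
    """
    if sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    s4 = sigma2_p**2
    denom = 2 * s4 + 3 * sigma2_av_add
    val = sigma2_av_add / denom
    if cov_matrix is None:
        return float(val), np.nan
    # gradient w.r.t. (sigma2_av_add, sigma2_p): denominator carries
    # 2 (sigma2_p)^2, so d denom / d sigma2_p = 4 sigma2_p
    g = np.array([2 * s4 / denom**2, -sigma2_av_add * 4 * sigma2_p / denom**2])
    se = float(np.sqrt(max(g @ np.asarray(cov_matrix) @ g, 0.0)))
    return float(val), se


def gcv_e(
    model_tag: str,
    sigma2_av_add: float | None = None,
    mean_resid_var: float | None = None,
    sigma2_astar: float | None = None,
) -> float:
    """Genetic coefficient of variation of the residual variance.

    M2 convention: sqrt(sigma2_av_add) / mean residual variance.
    M3 convention: lognormal genetic CV, sqrt(exp(sigma2_a*) - 1)
    (~ sigma_a* for small values).
    """
    tag = model_tag.lower()
    if tag == "m2":
        if sigma2_av_add is None or not mean_resid_var or mean_resid_var <= 0:
            raise ValueError("M2 path needs sigma2_av_add and mean_resid_var > 0")
        return float(np.sqrt(sigma2_av_add) / mean_resid_var)
    if tag == "m3":
        if sigma2_astar is None or sigma2_astar < 0:
            raise ValueError("M3 path needs sigma2_astar >= 0")
        return float(np.sqrt(np.expm1(sigma2_astar)))
    raise ValueError(f"unknown model tag {model_tag!r}")


def rmv(sigma_a_av: float, sigma2_a: float, sigma2_av: float) -> float:
    """Mean/residual-variance genetic correlation, clipped to [-1, 1]."""
    if sigma2_a <= 0 or sigma2_av <= 0:
        raise ValueError("variances must be positive to form a correlation")
    r = sigma_a_av / np.sqrt(sigma2_a * sigma2_av)
    if abs(r) > 1 + 1e-12:
        import warnings

        warnings.warn(f"r_mv = {r:.4f} outside [-1, 1]; clipping")
    return float(np.clip(r, -1.0, 1.0))


def h2_m3_levels(
    sigma2_a: float,
    sigma2_astar: float,
    xb_star_levels: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Level-specific heritabilities under the exponential model.

    h2_i = sigma2_a / (sigma2_a + exp(xb*_i + sigma2_a*/2)); the summary
    is the unweighted mean over levels unless record weights are given.
    """
    xb = np.asarray(xb_star_levels, dtype=float)
    h = sigma2_a / (sigma2_a + np.exp(xb + 0.5 * sigma2_astar))
    mean = float(np.average(h, weights=weights))
    return h, mean


@dataclass
class UniformityReport:
    """Uniformity parameters for one trait x model combination."""

    model_tag: str
    h2_mean: float
    hv2: float = np.nan
    hv2_se: float = np.nan
    sigma2_av_add: float = np.nan
    gcv_e: float = np.nan
    rmv: float = np.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.hv2) and not (0 <= self.hv2 <= 1):
            raise ValueError("hv2 must lie in [0, 1]")
        if np.isfinite(self.rmv) and abs(self.rmv) > 1:
            raise ValueError("|rmv| must be <= 1")
        if np.isfinite(self.gcv_e) and self.gcv_e < 0:
            raise ValueError("gcv_e must be >= 0")

    def to_text(self) -> str:
        d = asdict(self)
        extras = d.pop("extras")
        lines = [f"{k}\t{v}" for k, v in d.items()]
        lines += [f"{k}\t{v}" for k, v in extras.items()]
        return "\n".join(lines) + "\n"

    def to_tsv_row(self, trait: str = "trait") -> str:
        """One table-style row: trait, model, h2, hv2, GCV_E, rmv."""
        return "\t".join(
            [
                trait,
                self.model_tag,
                f"{self.h2_mean:.4g}",
                f"{self.hv2:.4g}",
                f"{self.gcv_e:.4g}",
                f"{self.rmv:.4g}",
            ]
        )


def report_from_dhglm(res, model_tag: str = "M2", method: str = "exact") -> UniformityReport:
    """Uniformity report from a DHGLM fit."""
    c = res.components
    mean_rv = res.mean_residual_variance()
    s_add = additive_scale_variance(c.sigma2_av, mean_rv, method=method)
    sigma2_p = c.sigma2_a + mean_rv
    cov = None
    if c.cov_params is not None:
        # delta method: sigma2_av_add = m^2 (exp(s2)-1), sigma2_p = sa2 + m
        d_add = mean_rv**2 * np.exp(c.sigma2_av)
        var_add = d_add**2 * c.cov_params[1, 1]
        var_p = c.cov_params[0, 0]
        cov_ap = d_add * c.cov_params[0, 1]
        cov = np.array([[var_add, cov_ap], [cov_ap, var_p]])
    val, se = hv2(s_add, sigma2_p, cov_matrix=cov)
    return UniformityReport(
        model_tag=model_tag,
        h2_mean=res.h2(),
        hv2=val,
        hv2_se=se,
        sigma2_av_add=s_add,
        gcv_e=gcv_e("m2", sigma2_av_add=s_add, mean_resid_var=mean_rv),
        rmv=res.rmv,
        extras={"sigma2_av_log": c.sigma2_av, "mean_resid_var": mean_rv},
    )


def report_from_gsevm(res, model_tag: str = "M3") -> UniformityReport:
    """Uniformity report from an exponential-model posterior."""
    return UniformityReport(
        model_tag=model_tag,
        h2_mean=res.h2(),
        gcv_e=gcv_e("m3", sigma2_astar=res.sigma2_astar),
        rmv=float(np.clip(res.rho, -1, 1)),
        sigma2_av_add=np.nan,
        extras={"sigma2_astar": res.sigma2_astar},
    )
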