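"""Homoscedastic animal model: REML correctness, oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from hetvar.animal_model import AnimalModel, VarianceComponents, h2_point, logdet_A
from hetvar.data import DesignBundle, build_design
from hetvar.pedigree import Pedigree, build_A
from hetvar.simulate import make_benchmark_dataset

from conftest import random_pedigree


def small_dataset(seed=1, n_f=10, n_off=60, sa=0.3, se=0.7, p_extra=1):
    """Random pedigree + phenotypes with known dense-REML oracle pieces."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n_f, n_f + n_off, seed)
    A = build_A(ped).entries
    idx = np.arange(n_f, n_f + n_off)
    m = len(idx)
    X = np.column_stack([np.ones(m)] + [rng.normal(size=m) for _ in range(p_extra)])
    Z = np.zeros((m, len(ped)))
    Z[np.arange(m), idx] = 1
    beta = rng.normal(size=X.shape[1])
    a = np.linalg.cholesky(A * sa + 1e-12 * np.eye(len(ped))) @ rng.standard_normal(len(ped))
    y = X @ beta + Z @ a + rng.normal(0, np.sqrt(se), m)
    db = DesignBundle(
        y=y, X=sparse.csr_matrix(X), animal_index=idx, n_pedigree=len(ped),
        cg_levels=pd.Index([0]), weights=np.ones(m),
        column_names=[f"c{i}" for i in range(X.shape[1])],
    )
    return db, ped, A, X, Z, y


def dense_reml(y, X, Z, A, sa, se, w=None):
    m = len(y)
    w = np.ones(m) if w is None else w
    V = Z @ (A * sa) @ Z.T + np.diag(se / w)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    return -0.5 * (ldV + ldX + y @ P @ y + (m - X.shape[1]) * np.log(2 * np.pi))


class TestLikelihood:
    @pytest.mark.parametrize("sa,se", [(0.3, 0.7), (0.05, 1.4), (0.9, 0.1)])
    def test_matches_dense_oracle(self, sa, se):
        db, ped, A, X, Z, y = small_dataset()
        am = AnimalModel(db, ped=ped)
        assert am.loglik(sa, se).loglik == pytest.approx(
            dense_reml(y, X, Z, A, sa, se), abs=1e-8
        )

    def test_matches_dense_oracle_weighted(self):
        db, ped, A, X, Z, y = small_dataset()
        rng = np.random.default_rng(5)
        w = rng.uniform(0.4, 2.5, len(y))
        db.weights = w
        am = AnimalModel(db, ped=ped)
        assert am.loglik(0.3, 0.7).loglik == pytest.approx(
            dense_reml(y, X, Z, A, 0.3, 0.7, w), abs=1e-8
        )

    def test_rescaling_translates_the_surface(self):
        # multiplying y by c shifts the REML surface: the optimum scales by c^2
        db, ped, A, X, Z, y = small_dataset()
        am = AnimalModel(db, ped=ped)
        c2 = 9.0
        db2 = DesignBundle(
            y=y * 3.0, X=db.X, animal_index=db.animal_index,
            n_pedigree=db.n_pedigree, cg_levels=db.cg_levels,
            weights=db.weights, column_names=db.column_names,
        )
        am2 = AnimalModel(db2, ped=ped)
        pts = [(0.3, 0.7), (0.1, 1.1), (0.7, 0.2)]
        diffs = [
            am2.loglik(c2 * sa, c2 * se).loglik - am.loglik(sa, se).loglik
            for sa, se in pts
        ]
        assert np.ptp(diffs) < 1e-8  # constant shift => identical argmax shape
        r1 = am.fit()
        r2 = am2.fit(init=(c2 * r1.sigma2_a, c2 * r1.sigma2_e))
        assert r2.sigma2_a == pytest.approx(c2 * r1.sigma2_a, rel=5e-4)
        assert r2.sigma2_e == pytest.approx(c2 * r1.sigma2_e, rel=5e-4)


class TestFitting:
    def test_null_signal_recovers_pure_noise(self):
        rng = np.random.default_rng(2)
        n = 2000
        ped = Pedigree(ids=pd.Index(range(n)), sire=np.full(n, -1), dam=np.full(n, -1))
        y = rng.normal(5.0, 1.0, n)
        db = DesignBundle(
            y=y, X=sparse.csr_matrix(np.ones((n, 1))), animal_index=np.arange(n),
            n_pedigree=n, cg_levels=pd.Index([0]), weights=np.ones(n),
            column_names=["mu"],
        )
        res = AnimalModel(db, ped=ped).fit()
        # unrelated animals: sigma2_a unidentifiable from sigma2_e individually,
        # but the total must match and the REML surface is flat in the split;
        # assert the total and that no spurious heritable signal SE-wise
        assert res.sigma2_a + res.sigma2_e == pytest.approx(1.0, rel=0.1)

    def test_half_sib_anova_oracle(self):
        # balanced half-sib families: REML matches the ANOVA estimators
        rng = np.random.default_rng(7)
        s, k = 100, 20
        sa, se = 0.2, 0.8
        sires = np.arange(s)
        sire_bv = rng.normal(0, np.sqrt(sa), s)
        n = s * k
        sire_of = np.repeat(sires, k)
        a = 0.5 * sire_bv[sire_of] + rng.normal(0, np.sqrt(0.75 * sa), n)
        y = 3.0 + a + rng.normal(0, np.sqrt(se), n)
        ped = Pedigree(
            ids=pd.Index([f"s{i}" for i in range(s)] + [f"p{i}" for i in range(n)]),
            sire=np.concatenate([np.full(s, -1), sire_of]),
            dam=np.full(s + n, -1),
        )
        db = DesignBundle(
            y=y, X=sparse.csr_matrix(np.ones((n, 1))),
            animal_index=np.arange(s, s + n), n_pedigree=s + n,
            cg_levels=pd.Index([0]), weights=np.ones(n), column_names=["mu"],
        )
        res = AnimalModel(db, ped=ped).fit()
        ybar_s = y.reshape(s, k).mean(axis=1)
        msb = k * np.var(ybar_s, ddof=1)
        msw = np.sum((y.reshape(s, k) - ybar_s[:, None]) ** 2) / (s * (k - 1))
        sa_anova = 4 * (msb - msw) / k
        se_anova = msw - 0.75 * sa_anova
        se_sa = res.vc.se.get("sigma2_a", 0.05)
        se_se = res.vc.se.get("sigma2_e", 0.05)
        assert res.sigma2_a == pytest.approx(sa_anova, abs=3 * se_sa)
        assert res.sigma2_e == pytest.approx(se_anova, abs=3 * se_se)

    def test_em_loglik_monotone_and_agrees_with_direct(self):
        db, ped, *_ = small_dataset(seed=3, n_off=80)
        am = AnimalModel(db, ped=ped)
        r_em = am.fit(method="em", tol=1e-10, max_iter=300)
        lls = np.asarray(r_em.em_loglik_trace)
        assert np.all(np.diff(lls) > -1e-8)
        r_nm = am.fit(init=(r_em.sigma2_a, r_em.sigma2_e))
        assert r_nm.loglik <= r_em.loglik + 1e-4

    def test_fixed_effects_are_gls_at_convergence(self):
        db, ped, A, X, Z, y = small_dataset(seed=4)
        res = AnimalModel(db, ped=ped).fit()
        V = Z @ (A * res.sigma2_a) @ Z.T + np.eye(len(y)) * res.sigma2_e
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(res.fe, beta_gls, atol=1e-8)

    def test_benchmark_recovery_smoke(self):
        ped, tab, truth = make_benchmark_dataset("fa_m3", n_animals=1200, seed=21)
        db = build_design(tab, ped)
        res = AnimalModel(db, ped=ped).fit()
        se = res.vc.se.get("sigma2_a", 0.02)
        assert res.sigma2_a == pytest.approx(0.05, abs=3.5 * se)
        assert res.vc.converged


class TestHeritability:
    def test_table_arithmetic(self):
        vc = VarianceComponents(sigma2_a=0.07, sigma2_e=0.30)
        assert round(h2_point(vc)[0], 2) == 0.19

    def test_limits(self):
        assert h2_point(VarianceComponents(0.0, 0.5))[0] == 0.0
        assert h2_point(VarianceComponents(0.5, 0.0))[0] == 1.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            h2_point(VarianceComponents(0.0, 0.0))

    def test_delta_method_se(self):
        vc = VarianceComponents(0.07, 0.30, cov_params=np.diag([9e-6, 9.6e-6]))
        h2, se = h2_point(vc)
        # direct delta arithmetic
        tot = 0.37
        g = np.array([0.30 / tot**2, -0.07 / tot**2])
        assert se == pytest.approx(np.sqrt(g @ np.diag([9e-6, 9.6e-6]) @ g))


def test_logdet_A_matches_dense():
    ped = random_pedigree(8, 120, seed=13)
    A = build_A(ped).entries
    assert logdet_A(ped) == pytest.approx(np.linalg.slogdet(A)[1], abs=1e-9)
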