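"""Numba kernel for the exponential variance-model Gibbs/Metropolis sampler.

One sweep updates, in order:
  1. mean-part fixed effects b        — single-site Gibbs (flat prior);
  2. mean-part breeding values a      — blocked Gibbs: one exact joint
                                        draw from the Gaussian full
                                        conditional via a sparse LDL'
                                        factorisation of the a-block
                                        (A-inverse pattern, symbolic
                                        analysis precomputed) — this is
                                        what keeps sigma2_a mixing fast;
  3. variance-part fixed effects b*   — adaptive random-walk Metropolis
                                        per coefficient;
  4. variance-part breeding values a* — Laplace-type independence
                                        Metropolis: a Gaussian built from
                                        the prior conditional plus the
                                        expected likelihood curvature
                                        (1/2 per record), exact accept
                                        ratio; pure Gibbs when the animal
                                        has no record;
  5. G (2x2 covariance of (a, a*))    — inverse-Wishart Gibbs draw.

Residuals r_i = y_i - x_i b - a_i and log-variances lv_i = x_i b* + a*_i
are maintained incrementally.  Proposal scales adapt only during burn-in.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _chol2(a, b, c):
    """Cholesky of [[a, b], [b, c]] -> (l11, l21, l22)."""
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(max(c - l21 * l21, 1e-300))
    return l11, l21, l22


@njit(cache=True)
def _draw_invwishart2(df, S11, S12, S22):
    """G ~ IW_2(df, S): draw W ~ Wishart(df, S^-1) by Bartlett, invert."""
    # inverse of S
    det = S11 * S22 - S12 * S12
    T11, T12, T22 = S22 / det, -S12 / det, S11 / det
    l11, l21, l22 = _chol2(T11, T12, T22)
    c1 = np.sqrt(np.random.gamma(0.5 * df, 2.0))
    c2 = np.sqrt(np.random.gamma(0.5 * (df - 1.0), 2.0))
    z = np.random.normal()
    # A = [[c1, 0], [z, c2]], LA = L @ A
    a11 = l11 * c1
    a21 = l21 * c1 + l22 * z
    a22 = l22 * c2
    W11 = a11 * a11
    W12 = a11 * a21
    W22 = a21 * a21 + a22 * a22
    detW = W11 * W22 - W12 * W12
    return W22 / detW, -W12 / detW, W11 / detW


@njit(cache=True)
def _ldl_numeric_buf(n, Ap, Ai, Ax, parent, Lp, Li, Lx, D, Y, pattern, flag, lnz):
    """Up-looking LDL' into preallocated buffers (full-pattern refactor)."""
    for i in range(n):
        flag[i] = -1
        lnz[i] = 0
        Y[i] = 0.0
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = pattern[top]
            yi = Y[i]
            Y[i] = 0.0
            for p in range(Lp[i], Lp[i] + lnz[i]):
                Y[Li[p]] -= Lx[p] * yi
            lki = yi / D[i]
            D[k] -= lki * yi
            Li[Lp[i] + lnz[i]] = k
            Lx[Lp[i] + lnz[i]] = lki
            lnz[i] += 1
            top += 1


@njit(cache=True)
def _ldl_solve(n, Lp, Li, Lx, D, lnz, b):
    """Solve L D L' x = b in place (unit lower L in CSC, strict below-diag)."""
    for j in range(n):
        xj = b[j]
        for p in range(Lp[j], Lp[j] + lnz[j]):
            b[Li[p]] -= Lx[p] * xj
    for j in range(n):
        b[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = b[j]
        for p in range(Lp[j], Lp[j] + lnz[j]):
            s -= Lx[p] * b[Li[p]]
        b[j] = s


@njit(cache=True)
def _ldl_sample(n, Lp, Li, Lx, D, lnz, z):
    """Transform z ~ N(0, I) into L^-T D^-1/2 z ~ N(0, S^-1), in place."""
    for j in range(n):
        z[j] /= np.sqrt(D[j])
    for j in range(n - 1, -1, -1):
        s = z[j]
        for p in range(Lp[j], Lp[j] + lnz[j]):
            s -= Lx[p] * z[Li[p]]
        z[j] = s


@njit(cache=True)
def run_sampler(
    y,
    Xp, Xi, Xd,          # CSR of X (n x p), shared by mean and variance parts
    XTp, XTi, XTd,       # CSC of X (column access)
    anim,                # record -> animal code (n)
    rec_of,              # animal -> record id or -1 (q)
    Ap, Ai, Ad,          # CSR of A^-1 (q x q)
    Sp_p, Sp_i, Sp_x,    # CSC of the permuted A^-1 (pattern of the a-block)
    diag_pos,            # position of each diagonal entry in Sp columns
    perm_a, iperm_a,     # fill-reducing permutation and its inverse
    parent_a, Lp_a,      # LDL symbolic analysis of the permuted pattern
    nu0, V011, V022,     # inverse-Wishart prior df and scale diagonal
    n_iter, burn_in, thin,
    seed,
    sigma2_a0, sigma2_astar0,
    b0, bs0,             # initial fixed effects (p,)
    use_likelihood=1,    # 0: prior-recovery mode (no data terms)
    update_var_part=1,   # 0: freeze a* at 0 (residual variance exp(X b*) only)
):
    np.random.seed(seed)
    n = y.shape[0]
    p = XTp.shape[0] - 1
    q = Ap.shape[0] - 1

    b = b0.copy()
    bs = bs0.copy()
    a = np.zeros(q)
    astar = np.zeros(q)
    G11, G12, G22 = sigma2_a0, 0.0, sigma2_astar0

    # residuals and log-variances
    r = np.empty(n)
    lv = np.empty(n)
    for i in range(n):
        xb = 0.0
        xbs = 0.0
        for k in range(Xp[i], Xp[i + 1]):
            xb += Xd[k] * b[Xi[k]]
            xbs += Xd[k] * bs[Xi[k]]
        r[i] = y[i] - xb - a[anim[i]]
        lv[i] = xbs + astar[anim[i]]
    vinv = np.exp(-lv)

    # adaptive RW scales for b*
    scale_bs = np.empty(p)
    for j in range(p):
        s2 = 0.0
        for k in range(XTp[j], XTp[j + 1]):
            s2 += XTd[k] * XTd[k]
        scale_bs[j] = 2.4 / np.sqrt(0.5 * s2 + 1e-12)
    acc_bs = np.zeros(p)
    try_bs = np.zeros(p)
    acc_as = 0.0
    try_as = 0.0
    # parameter-expansion scale moves
    scale_px_a = 0.2
    scale_px_s = 0.2
    acc_px_a = 0.0
    try_px_a = 0.0
    acc_px_s = 0.0
    try_px_s = 0.0

    # buffers for the blocked a-update
    nnzL = Lp_a[q]
    Li_a = np.zeros(nnzL, dtype=np.int64)
    Lx_a = np.zeros(nnzL)
    D_a = np.zeros(q)
    Yw = np.zeros(q)
    patw = np.empty(q, dtype=np.int64)
    flagw = np.empty(q, dtype=np.int64)
    lnzw = np.zeros(q, dtype=np.int64)
    Sx_buf = np.empty(Sp_p[q])
    m_vec = np.empty(q)
    rhs = np.empty(q)
    zw = np.empty(q)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    # columns: G11, G22, G12, rho, b (p), bs (p)
    ncol = 4 + 2 * p
    draws = np.empty((n_keep, ncol))
    a_mean = np.zeros(q)
    astar_mean = np.zeros(q)
    kept = 0

    for it in range(n_iter):
        detG = G11 * G22 - G12 * G12
        gi11 = G22 / detG
        gi12 = -G12 / detG
        gi22 = G11 / detG

        # -- 1. fixed effects b (Gibbs, flat prior) -------------------------
        for j in range(p if use_likelihood == 1 else 0):
            prec = 0.0
            lin = 0.0
            for k in range(XTp[j], XTp[j + 1]):
                i = XTi[k]
                x = XTd[k]
                w = vinv[i]
                prec += x * x * w
                lin += x * w * (r[i] + x * b[j])
            if prec <= 0.0:
                continue
            newb = lin / prec + np.random.normal() / np.sqrt(prec)
            diff = newb - b[j]
            if diff != 0.0:
                b[j] = newb
                for k in range(XTp[j], XTp[j + 1]):
                    r[XTi[k]] -= XTd[k] * diff

        # -- 2. breeding values a (blocked Gibbs via sparse LDL') -----------
        # conditional: prec = gi11 A^-1 + diag(1/v at records),
        #              lin  = (y - Xb)/v at records - gi12 A^-1 a*
        for ii in range(q):
            s = 0.0
            for k in range(Ap[ii], Ap[ii + 1]):
                s += Ad[k] * astar[Ai[k]]
            m_vec[ii] = -gi12 * s
        if use_likelihood == 1:
            for ii in range(q):
                rec = rec_of[ii]
                if rec >= 0:
                    m_vec[ii] += vinv[rec] * (r[rec] + a[ii])
        # assemble permuted coefficient values
        for pp in range(Sp_p[q]):
            Sx_buf[pp] = gi11 * Sp_x[pp]
        if use_likelihood == 1:
            for jj in range(q):
                rec = rec_of[perm_a[jj]]
                if rec >= 0:
                    Sx_buf[diag_pos[jj]] += vinv[rec]
        _ldl_numeric_buf(q, Sp_p, Sp_i, Sx_buf, parent_a, Lp_a,
                         Li_a, Lx_a, D_a, Yw, patw, flagw, lnzw)
        for jj in range(q):
            rhs[jj] = m_vec[perm_a[jj]]
            zw[jj] = np.random.normal()
        _ldl_solve(q, Lp_a, Li_a, Lx_a, D_a, lnzw, rhs)
        _ldl_sample(q, Lp_a, Li_a, Lx_a, D_a, lnzw, zw)
        for jj in range(q):
            newa = rhs[jj] + zw[jj]
            ii = perm_a[jj]
            rec = rec_of[ii]
            if rec >= 0:
                r[rec] -= newa - a[ii]
            a[ii] = newa

        # -- 3. variance-part fixed effects b* (adaptive RW MH) -------------
        for j in range(p if use_likelihood == 1 else 0):
            s = scale_bs[j]
            prop = np.random.normal() * s
            if prop == 0.0:
                continue
            dlp = 0.0
            for k in range(XTp[j], XTp[j + 1]):
                i = XTi[k]
                dlv = XTd[k] * prop
                # -(1/2)[dlv + r^2 (e^{-lv-dlv} - e^{-lv})]
                dlp += -0.5 * (dlv + r[i] * r[i] * vinv[i] * (np.exp(-dlv) - 1.0))
            try_bs[j] += 1.0
            if np.log(np.random.random()) < dlp:
                acc_bs[j] += 1.0
                bs[j] += prop
                for k in range(XTp[j], XTp[j + 1]):
                    i = XTi[k]
                    lv[i] += XTd[k] * prop
                    vinv[i] = np.exp(-lv[i])
            if it < burn_in and try_bs[j] >= 50.0:
                rate = acc_bs[j] / try_bs[j]
                scale_bs[j] *= np.exp((rate - 0.40) * 0.8)
                acc_bs[j] = 0.0
                try_bs[j] = 0.0

        # -- 4. variance-part breeding values a* ----------------------------
        for ii in range(q if update_var_part == 1 else 0):
            aii = 0.0
            lin = 0.0
            for k in range(Ap[ii], Ap[ii + 1]):
                jj = Ai[k]
                w = Ad[k]
                if jj == ii:
                    aii = w
                    lin -= gi12 * w * a[jj]
                else:
                    lin -= gi22 * w * astar[jj] + gi12 * w * a[jj]
            prior_prec = gi22 * aii
            m0 = lin / prior_prec
            rec = rec_of[ii] if use_likelihood == 1 else -1
            if rec < 0:
                astar[ii] = m0 + np.random.normal() / np.sqrt(prior_prec)
                continue
            # Laplace-style independence proposal around the prior mean
            cur = astar[ii]
            base = lv[rec] - cur           # x_i b*, fixed during this update
            r2 = r[rec] * r[rec]
            # gradient of likelihood at m0
            g = -0.5 * (1.0 - r2 * np.exp(-(base + m0)))
            P = prior_prec + 0.5
            mp = m0 + g / P
            sd = 1.0 / np.sqrt(P)
            prop = mp + np.random.normal() * sd
            # log target: prior + likelihood
            lp_prop = (
                -0.5 * prior_prec * (prop - m0) ** 2
                - 0.5 * ((base + prop) + r2 * np.exp(-(base + prop)))
            )
            lp_cur = (
                -0.5 * prior_prec * (cur - m0) ** 2
                - 0.5 * ((base + cur) + r2 * np.exp(-(base + cur)))
            )
            lq_prop = -0.5 * P * (prop - mp) ** 2
            lq_cur = -0.5 * P * (cur - mp) ** 2
            try_as += 1.0
            if np.log(np.random.random()) < (lp_prop - lp_cur) - (lq_prop - lq_cur):
                acc_as += 1.0
                astar[ii] = prop
                lv[rec] = base + prop
                vinv[rec] = np.exp(-lv[rec])

        # -- 4b. parameter-expansion scale moves ----------------------------
        # jointly rescale (a, G-row) or (a*, G-column) by c = e^eps; the
        # G (x) A quadratic form is invariant, leaving
        #   log alpha = delta-loglik - nu0 log c - V/2 * gi (c^-2 - 1)
        # after the inverse-Wishart prior and the Jacobian c^(q+3) cancel
        # against the prior normaliser c^-q and |G'| terms.
        if use_likelihood == 1:
            eps = np.random.normal() * scale_px_a
            c = np.exp(eps)
            dll = 0.0
            for i in range(n):
                rnew = r[i] + (1.0 - c) * a[anim[i]]
                dll += -0.5 * (rnew * rnew - r[i] * r[i]) * vinv[i]
            la = dll - nu0 * eps - 0.5 * V011 * gi11 * (1.0 / (c * c) - 1.0)
            try_px_a += 1.0
            if np.log(np.random.random()) < la:
                acc_px_a += 1.0
                for ii in range(q):
                    a[ii] *= c
                for i in range(n):
                    r[i] = r[i] - (c - 1.0) / c * a[anim[i]]
                G11, G12 = c * c * G11, c * G12
                detG = G11 * G22 - G12 * G12
                gi11 = G22 / detG
                gi12 = -G12 / detG
                gi22 = G11 / detG
            if it < burn_in and try_px_a >= 50.0:
                scale_px_a *= np.exp((acc_px_a / try_px_a - 0.30) * 0.8)
                acc_px_a = 0.0
                try_px_a = 0.0

        if use_likelihood == 1 and update_var_part == 1:
            eps = np.random.normal() * scale_px_s
            c = np.exp(eps)
            dll = 0.0
            for i in range(n):
                dlv = (c - 1.0) * astar[anim[i]]
                dll += -0.5 * (dlv + r[i] * r[i] * vinv[i] * (np.exp(-dlv) - 1.0))
            la = dll - nu0 * eps - 0.5 * V022 * gi22 * (1.0 / (c * c) - 1.0)
            try_px_s += 1.0
            if np.log(np.random.random()) < la:
                acc_px_s += 1.0
                for ii in range(q):
                    astar[ii] *= c
                for i in range(n):
                    lv[i] = lv[i] + (c - 1.0) * astar[anim[i]] / c
                    vinv[i] = np.exp(-lv[i])
                G22, G12 = c * c * G22, c * G12
            if it < burn_in and try_px_s >= 50.0:
                scale_px_s *= np.exp((acc_px_s / try_px_s - 0.30) * 0.8)
                acc_px_s = 0.0
                try_px_s = 0.0

        # -- 5. genetic covariance G (inverse-Wishart Gibbs) ----------------
        S11 = 0.0
        S12 = 0.0
        S22 = 0.0
        for ii in range(q):
            for k in range(Ap[ii], Ap[ii + 1]):
                jj = Ai[k]
                w = Ad[k]
                S11 += w * a[ii] * a[jj]
                S12 += w * a[ii] * astar[jj]
                S22 += w * astar[ii] * astar[jj]
        G11, G12, G22 = _draw_invwishart2(
            nu0 + q, V011 + S11, S12, V022 + S22
        )

        # -- record ----------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            rho = G12 / np.sqrt(G11 * G22)
            draws[kept, 0] = G11
            draws[kept, 1] = G22
            draws[kept, 2] = G12
            draws[kept, 3] = rho
            for j in range(p):
                draws[kept, 4 + j] = b[j]
                draws[kept, 4 + p + j] = bs[j]
            kept += 1
            for ii in range(q):
                a_mean[ii] += a[ii]
                astar_mean[ii] += astar[ii]

    if kept > 0:
        for ii in range(q):
            a_mean[ii] /= kept
            astar_mean[ii] /= kept
    acc_rate_as = acc_as / max(try_as, 1.0)
    # post-burn-in b* acceptance: report last adaptation window rate
    acc_rate_bs = np.empty(p)
    for j in range(p):
        acc_rate_bs[j] = acc_bs[j] / max(try_bs[j], 1.0)
    return draws[:kept], a_mean, astar_mean, acc_rate_as, acc_rate_bs, scale_bs
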