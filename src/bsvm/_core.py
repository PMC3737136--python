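"""Numerical core: weighted SMO for the RBF soft-margin SVM and the
backward-elimination pipeline, compiled with numba.

The permutation and power studies re-run the entire pipeline (variant
classification -> weighting -> directional collapsing -> backward selection
-> R^2) tens of thousands of times.  To make that tractable on one CPU the
core works on *genotype patterns*: individuals sharing the same row of
minor-allele counts are merged into one point per (pattern, phenotype) with
an integer multiplicity, and the dual box constraint is scaled by the
multiplicity (0 <= alpha <= C * mult), which is exactly equivalent to
duplicating the point.  With rare variants the number of distinct patterns
is tiny compared to the sample size.

Scheme codes: 0=RM, 1=WSt, 2=RBt, 3=Fp, 4=EREC.
R^2 modes: 0 = continuous decision values f(x), 1 = thresholded labels.
"""

import math

import numpy as np
from numba import njit

SCHEME_CODES = {"RM": 0, "WSt": 1, "RBt": 2, "Fp": 3, "EREC": 4}

_STD_EPS = 1e-12


@njit(cache=True)
def _binom_sf(k, m, p):
    """P(X >= k) for X ~ Binomial(m, p), by direct log-space summation."""
    if k <= 0:
        return 1.0
    if k > m:
        return 0.0
    lp = math.log(p)
    lq = math.log1p(-p)
    lgm = math.lgamma(m + 1.0)
    s = 0.0
    for j in range(k, m + 1):
        lt = (lgm - math.lgamma(j + 1.0) - math.lgamma(m - j + 1.0)
              + j * lp + (m - j) * lq)
        s += math.exp(lt)
    if s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def _compute_weights(m_case, m_ctrl, n1, n2, scheme, erec_delta, sum_g2):
    """Per-variant category (1=risk, 0=nonrisk) and weight for one scheme.

    Monomorphic variants (m_case + m_ctrl == 0) must have been dropped by
    the caller.
    """
    M = m_case.shape[0]
    n = float(n1 + n2)
    w = np.empty(M)
    cat = np.empty(M, np.int8)
    for i in range(M):
        mc = m_case[i]
        mu = m_ctrl[i]
        m = mc + mu
        risk = mc > mu
        cat[i] = 1 if risk else 0
        corr = (m + 2.0) / (m + 1.0)
        lam_case = (mc + 1.0) / (2.0 * n1 + 2.0)
        lam_ctrl = (mu + 1.0) / (2.0 * n2 + 2.0)
        if risk:
            rm = (lam_case / lam_ctrl) * corr
        else:
            rm = (lam_ctrl / lam_case) * corr
        if scheme == 0:  # RM: Poisson likelihood-ratio risk measure
            w[i] = rm
        elif scheme == 1:  # WSt: Madsen-Browning control-frequency weight
            q = (mu + 1.0) / (2.0 * n2 + 2.0)
            w[i] = 1.0 / math.sqrt(n * q * (1.0 - q))
        elif scheme == 2:  # RBt: replication-based binomial-tail weight
            if risk:
                sf = _binom_sf(int(mc), int(m), n1 / n)
            else:
                sf = _binom_sf(int(mu), int(m), n2 / n)
            if sf <= 0.0:
                wv = 745.0  # -log of the smallest subnormal double
            else:
                wv = -math.log(sf)
            if not np.isfinite(wv) or wv <= 0.0:
                wv = rm
            w[i] = wv
        elif scheme == 3:  # Fp: pooled-frequency weight
            ph = (m + 1.0) / (2.0 * n + 2.0)
            w[i] = 1.0 / math.sqrt(ph * (1.0 - ph))
        else:  # EREC: one-step logistic coefficient estimate plus offset
            ybar = n1 / n
            score = mc - ybar * m
            info = ybar * (1.0 - ybar) * (sum_g2[i] - m * m / n)
            if info > 1e-12:
                beta = score / info
            else:
                beta = 0.0
            v = beta + erec_delta
            cat[i] = 1 if v >= 0.0 else 0
            wv = abs(v)
            if not np.isfinite(wv) or wv <= 1e-12:
                wv = rm
                cat[i] = 1 if risk else 0
            w[i] = wv
    return w, cat


@njit(cache=True)
def _rbf_matrix(x1, x2, gamma):
    u = x1.shape[0]
    K = np.empty((u, u))
    for a in range(u):
        K[a, a] = 1.0
        for c in range(a):
            d1 = x1[a] - x1[c]
            d2 = x2[a] - x2[c]
            v = math.exp(-gamma * (d1 * d1 + d2 * d2))
            K[a, c] = v
            K[c, a] = v
    return K


@njit(cache=True)
def _smo_solve(K, y, ub, tol, max_iter, alpha):
    """Maximal-violating-pair SMO for the dual QP

        min 0.5 a'Qa - e'a,  Q_kj = y_k y_j K_kj,  0 <= a <= ub,  y'a = 0.

    ``alpha`` is used as a (feasible) warm start and updated in place.
    Returns the gradient G = Qa - e and the bias b; decision values follow
    as f_k = y_k (G_k + 1) + b.  Pair updates keep y'a = 0 and the box
    satisfied exactly.
    """
    u = y.shape[0]
    G = np.empty(u)
    for k in range(u):
        g = -1.0
        for j in range(u):
            aj = alpha[j]
            if aj != 0.0:
                g += y[k] * y[j] * K[k, j] * aj
        G[k] = g
    for _ in range(max_iter):
        # first-order choice of i over I_up; second-order choice of j over
        # I_low (libsvm WSS2): maximise the objective decrease b^2 / a
        Gmax = -1e300
        Gmin = 1e300
        i = -1
        for k in range(u):
            yk = y[k]
            ak = alpha[k]
            v = -yk * G[k]
            if (yk > 0.0 and ak < ub[k]) or (yk < 0.0 and ak > 0.0):
                if v > Gmax:
                    Gmax = v
                    i = k
            if (yk > 0.0 and ak > 0.0) or (yk < 0.0 and ak < ub[k]):
                if v < Gmin:
                    Gmin = v
        if i < 0 or Gmax - Gmin < tol:
            break
        j = -1
        best_gain = -1.0
        Kii = K[i, i]
        for k in range(u):
            yk = y[k]
            ak = alpha[k]
            if (yk > 0.0 and ak > 0.0) or (yk < 0.0 and ak < ub[k]):
                diff = Gmax + yk * G[k]  # = Gmax - (-y_k G_k) > 0 if viable
                if diff > 0.0:
                    quad = Kii + K[k, k] - 2.0 * K[i, k]
                    if quad < 1e-12:
                        quad = 1e-12
                    gain = diff * diff / quad
                    if gain > best_gain:
                        best_gain = gain
                        j = k
        if j < 0:
            break
        quad = Kii + K[j, j] - 2.0 * K[i, j]
        if quad < 1e-12:
            quad = 1e-12
        lam = (Gmax + y[j] * G[j]) / quad
        if y[i] > 0.0:
            cap = ub[i] - alpha[i]
        else:
            cap = alpha[i]
        if cap < lam:
            lam = cap
        if y[j] > 0.0:
            cap = alpha[j]
        else:
            cap = ub[j] - alpha[j]
        if cap < lam:
            lam = cap
        if lam <= 0.0:
            break
        alpha[i] += y[i] * lam
        alpha[j] -= y[j] * lam
        for k in range(u):
            G[k] += y[k] * lam * (K[k, i] - K[k, j])
    # bias from the final violating bounds
    Gmax = -1e300
    Gmin = 1e300
    for k in range(u):
        yk = y[k]
        ak = alpha[k]
        v = -yk * G[k]
        if (yk > 0.0 and ak < ub[k]) or (yk < 0.0 and ak > 0.0):
            if v > Gmax:
                Gmax = v
        if (yk > 0.0 and ak > 0.0) or (yk < 0.0 and ak < ub[k]):
            if v < Gmin:
                Gmin = v
    if Gmax < -1e299 and Gmin > 1e299:
        b = 0.0
    elif Gmax < -1e299:
        b = Gmin
    elif Gmin > 1e299:
        b = Gmax
    else:
        b = 0.5 * (Gmax + Gmin)
    return G, b


@njit(cache=True)
def _fit_point_set(x1, x2, y, mult, n, tbar, C, gamma, standardize, tol,
                   max_iter, alpha, r2_mode):
    """Fit the RBF SVM on weighted points and return the model R^2.

    ``alpha`` is warm-start input and holds the solution on return.
    Covariates are standardised with multiplicity-weighted moments over all
    n individuals.  If both covariates are constant across the sample the
    decision function degenerates to the constant label mean and R^2 is 0.
    """
    u = x1.shape[0]
    m1 = 0.0
    m2 = 0.0
    for k in range(u):
        m1 += mult[k] * x1[k]
        m2 += mult[k] * x2[k]
    m1 /= n
    m2 /= n
    v1 = 0.0
    v2 = 0.0
    for k in range(u):
        v1 += mult[k] * (x1[k] - m1) ** 2
        v2 += mult[k] * (x2[k] - m2) ** 2
    s1 = math.sqrt(v1 / n)
    s2 = math.sqrt(v2 / n)
    if s1 <= _STD_EPS and s2 <= _STD_EPS:
        for k in range(u):
            alpha[k] = 0.0
        return 0.0
    z1 = np.empty(u)
    z2 = np.empty(u)
    if standardize:
        for k in range(u):
            z1[k] = (x1[k] - m1) / s1 if s1 > _STD_EPS else 0.0
            z2[k] = (x2[k] - m2) / s2 if s2 > _STD_EPS else 0.0
    else:
        for k in range(u):
            z1[k] = x1[k]
            z2[k] = x2[k]
    K = _rbf_matrix(z1, z2, gamma)
    ub = np.empty(u)
    for k in range(u):
        ub[k] = C * mult[k]
    G, b = _smo_solve(K, y, ub, tol, max_iter, alpha)
    ss_tot = n * (1.0 - tbar * tbar)
    if r2_mode == 0:
        # calibrated estimated status: affine least-squares map of the
        # decision values onto the labels, so R^2 = corr(t, f)^2 — zero for
        # an uninformative fit, monotone in fit quality
        fbar = 0.0
        for k in range(u):
            fbar += mult[k] * (y[k] * (G[k] + 1.0) + b)
        fbar /= n
        sxy = 0.0
        sxx = 0.0
        for k in range(u):
            f = y[k] * (G[k] + 1.0) + b
            sxy += mult[k] * (f - fbar) * (y[k] - tbar)
            sxx += mult[k] * (f - fbar) ** 2
        if sxx <= 1e-300:
            return 0.0
        return (sxy * sxy) / (sxx * ss_tot)
    ss_res = 0.0
    for k in range(u):
        f = y[k] * (G[k] + 1.0) + b
        if r2_mode == 1:
            f = 1.0 if f > 0.0 else -1.0
        ss_res += mult[k] * (y[k] - f) ** 2
    return 1.0 - ss_res / ss_tot


@njit(cache=True)
def _backward_select_core(pat, n_case_p, n_ctrl_p, w, cat, n1, n2, C, gamma,
                          standardize, tol, max_iter, r2_mode):
    """Backward elimination of variants maximising R^2.

    Each round computes R^2 with every remaining variant left out of its
    burden covariate; the best removal (ties -> lowest variant index) is
    accepted while its R^2 is >= the current R^2.  A removal that would
    leave both collapsed covariates identically zero is never offered.

    Returns (r2_final, removed index array in order, accepted R^2 path
    including the initial fit, number of SVM fits performed).
    """
    P, M = pat.shape
    n = float(n1 + n2)
    tbar = (n1 - n2) / n
    u = 0
    for p in range(P):
        if n_case_p[p] > 0:
            u += 1
        if n_ctrl_p[p] > 0:
            u += 1
    pt_p = np.empty(u, np.int64)
    y = np.empty(u)
    mult = np.empty(u)
    t = 0
    for p in range(P):
        if n_case_p[p] > 0:
            pt_p[t] = p
            y[t] = 1.0
            mult[t] = n_case_p[p]
            t += 1
        if n_ctrl_p[p] > 0:
            pt_p[t] = p
            y[t] = -1.0
            mult[t] = n_ctrl_p[p]
            t += 1
    s1 = np.zeros(P)
    s2 = np.zeros(P)
    for i in range(M):
        wi = w[i]
        if cat[i] == 1:
            for p in range(P):
                s1[p] += wi * pat[p, i]
        else:
            for p in range(P):
                s2[p] += wi * pat[p, i]
    active = np.ones(M, np.bool_)
    x1 = np.empty(u)
    x2 = np.empty(u)
    alpha = np.zeros(u)
    alpha_best = np.zeros(u)
    alpha_cand = np.zeros(u)
    for k in range(u):
        x1[k] = s1[pt_p[k]]
        x2[k] = s2[pt_p[k]]
    r2_cur = _fit_point_set(x1, x2, y, mult, n, tbar, C, gamma, standardize,
                            tol, max_iter, alpha, r2_mode)
    n_fits = 1
    removed = np.empty(M, np.int64)
    r2_path = np.empty(M + 1)
    r2_path[0] = r2_cur
    n_removed = 0
    c1 = np.empty(P)
    c2 = np.empty(P)
    while True:
        best_i = -1
        best_r2 = -1e300
        for i in range(M):
            if not active[i]:
                continue
            wi = w[i]
            if cat[i] == 1:
                for p in range(P):
                    c1[p] = s1[p] - wi * pat[p, i]
                    c2[p] = s2[p]
            else:
                for p in range(P):
                    c1[p] = s1[p]
                    c2[p] = s2[p] - wi * pat[p, i]
            allzero = True
            for p in range(P):
                if c1[p] != 0.0 or c2[p] != 0.0:
                    allzero = False
                    break
            if allzero:
                continue
            for k in range(u):
                x1[k] = c1[pt_p[k]]
                x2[k] = c2[pt_p[k]]
                alpha_cand[k] = alpha[k]
            r2_i = _fit_point_set(x1, x2, y, mult, n, tbar, C, gamma,
                                  standardize, tol, max_iter, alpha_cand,
                                  r2_mode)
            n_fits += 1
            if r2_i > best_r2:
                best_r2 = r2_i
                best_i = i
                for k in range(u):
                    alpha_best[k] = alpha_cand[k]
        if best_i < 0 or best_r2 < r2_cur:
            break
        i = best_i
        wi = w[i]
        if cat[i] == 1:
            for p in range(P):
                s1[p] -= wi * pat[p, i]
        else:
            for p in range(P):
                s2[p] -= wi * pat[p, i]
        active[i] = False
        r2_cur = best_r2
        for k in range(u):
            alpha[k] = alpha_best[k]
        removed[n_removed] = i
        n_removed += 1
        r2_path[n_removed] = r2_cur
    return r2_cur, removed[:n_removed], r2_path[:n_removed + 1], n_fits


@njit(cache=True)
def _pipeline_r2(pat, n_case_p, n_ctrl_p, n1, n2, scheme, erec_delta, sum_g2,
                 C, gamma, standardize, tol, max_iter, r2_mode):
    """Full pipeline on pattern-compressed data: classify and weight
    variants from the (possibly permuted) per-pattern case counts, collapse,
    backward-select, and return the final R^2."""
    P, M = pat.shape
    m_case = np.zeros(M)
    m_ctrl = np.zeros(M)
    for p in range(P):
        ncp = n_case_p[p]
        nup = n_ctrl_p[p]
        for i in range(M):
            g = pat[p, i]
            if g != 0.0:
                m_case[i] += ncp * g
                m_ctrl[i] += nup * g
    w, cat = _compute_weights(m_case, m_ctrl, n1, n2, scheme, erec_delta,
                              sum_g2)
    r2, _, _, _ = _backward_select_core(pat, n_case_p, n_ctrl_p, w, cat, n1,
                                        n2, C, gamma, standardize, tol,
                                        max_iter, r2_mode)
    return r2


@njit(cache=True)
def _subset_r2(pat, n_case_p, n_ctrl_p, w, cat, keep, n1, n2, C, gamma,
               standardize, tol, max_iter, r2_mode):
    """R^2 of a single SVM fit on the variants flagged in ``keep`` (no
    selection loop); used by the per-variant permutation test."""
    P, M = pat.shape
    n = float(n1 + n2)
    tbar = (n1 - n2) / n
    u = 0
    for p in range(P):
        if n_case_p[p] > 0:
            u += 1
        if n_ctrl_p[p] > 0:
            u += 1
    y = np.empty(u)
    mult = np.empty(u)
    x1 = np.zeros(u)
    x2 = np.zeros(u)
    t = 0
    for p in range(P):
        sr = 0.0
        sn = 0.0
        for i in range(M):
            if keep[i] and pat[p, i] != 0.0:
                if cat[i] == 1:
                    sr += w[i] * pat[p, i]
                else:
                    sn += w[i] * pat[p, i]
        if n_case_p[p] > 0:
            y[t] = 1.0
            mult[t] = n_case_p[p]
            x1[t] = sr
            x2[t] = sn
            t += 1
        if n_ctrl_p[p] > 0:
            y[t] = -1.0
            mult[t] = n_ctrl_p[p]
            x1[t] = sr
            x2[t] = sn
            t += 1
    alpha = np.zeros(u)
    return _fit_point_set(x1, x2, y, mult, n, tbar, C, gamma, standardize,
                          tol, max_iter, alpha, r2_mode)
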