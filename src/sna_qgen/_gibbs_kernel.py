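"""Numba kernel for the single-site Gibbs sweep of the animal model.

One kernel serves univariate and bivariate models: every location effect is a
t-vector (t = number of traits, 1 or 2) drawn from its Gaussian full
conditional under the mixed-model equations; the (co)variance matrices G0
(additive genetic, structured by A through its sparse inverse), C0 (pen) and
R0 (residual) are drawn from their inverse-Wishart full conditionals.  All
small t x t linear algebra is hand-rolled so the per-animal inner loop stays
free of LAPACK call overhead.

All randomness goes through numba's internal RNG seeded once at kernel entry,
so chains are bit-reproducible for a given seed and configuration.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _chol(P, L):
    """Lower Cholesky of P into L; returns False if P is not PD."""
    t = P.shape[0]
    for i in range(t):
        for j in range(i + 1):
            s = P[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0 or not np.isfinite(s):
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True, inline="always")
def _inv_spd(M, L, out):
    """out = M^{-1} for SPD M via Cholesky; returns False if not PD."""
    t = M.shape[0]
    if not _chol(M, L):
        return False
    for col in range(t):
        # forward solve L w = e_col, reusing out[:, col] as workspace
        for i in range(t):
            s = 1.0 if i == col else 0.0
            for k in range(i):
                s -= L[i, k] * out[k, col]
            out[i, col] = s / L[i, i]
        # back solve L^T x = w
        for i in range(t - 1, -1, -1):
            s = out[i, col]
            for k in range(i + 1, t):
                s -= L[k, i] * out[k, col]
            out[i, col] = s / L[i, i]
    return True


@njit(cache=True, inline="always")
def _draw_mvn_prec(P, rhs, L, w, out):
    """Draw N(P^{-1} rhs, P^{-1}) into out; returns False if P not PD."""
    t = P.shape[0]
    if not _chol(P, L):
        return False
    for i in range(t):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * w[k]
        w[i] = s / L[i, i]
    for i in range(t):
        w[i] += np.random.standard_normal()
    for i in range(t - 1, -1, -1):
        s = w[i]
        for k in range(i + 1, t):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    return True


@njit(cache=True)
def _draw_invwishart(scale, df, out):
    """Draw out ~ InvWishart(scale, df) (mean scale/(df - t - 1)).

    Bartlett decomposition of W ~ Wishart(df, scale^{-1}); out = W^{-1}.
    Returns False on numerical failure.
    """
    t = scale.shape[0]
    L = np.empty((t, t))
    Vinv = np.empty((t, t))
    if not _inv_spd(scale, L, Vinv):
        return False
    Lv = np.zeros((t, t))
    if not _chol(Vinv, Lv):
        return False
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    # T = Lv @ A (both lower triangular)
    T = np.zeros((t, t))
    for i in range(t):
        for j in range(t):
            s = 0.0
            for k in range(t):
                s += Lv[i, k] * A[k, j]
            T[i, j] = s
    W = np.empty((t, t))
    for i in range(t):
        for j in range(t):
            s = 0.0
            for k in range(t):
                s += T[i, k] * T[j, k]
            W[i, j] = s
    if not _inv_spd(W, L, out):
        return False
    return True


@njit(cache=True)
def gibbs_kernel(
    y, miss, X, sxx, rec_animal, rec_pen,
    ainv_indptr, ainv_indices, ainv_data,
    rec_of_animal, pen_indptr, pen_records,
    b, a, c, G0, C0, R0,
    Sg, nu_g, Sc_prior, nu_c, Sr, nu_r,
    n_iter, burn_in, thin, seed, sample_location,
):
    """Run the Gibbs chain; mutates b/a/c/G0/C0/R0, returns saved draws.

    Returns (G0_draws, C0_draws, R0_draws, err) where err is 0 on success,
    or 1 + the iteration index at which a conditional scale matrix stopped
    being positive definite / a draw went non-finite.
    """
    np.random.seed(seed)
    n, t = y.shape
    p = X.shape[1]
    q = a.shape[0]
    npen = c.shape[0]
    n_save = (n_iter - burn_in + thin - 1) // thin

    G0_draws = np.empty((n_save, t, t))
    C0_draws = np.empty((n_save, t, t))
    R0_draws = np.empty((n_save, t, t))

    # scratch
    P = np.empty((t, t))
    L = np.empty((t, t))
    rhs = np.empty(t)
    w = np.empty(t)
    out = np.empty(t)
    G0inv = np.empty((t, t))
    C0inv = np.empty((t, t))
    R0inv = np.empty((t, t))
    sv = np.empty(t)
    u = np.empty((q, t))
    Sa = np.empty((t, t))
    Sc = np.empty((t, t))
    Se = np.empty((t, t))

    if not _inv_spd(G0, L, G0inv):
        return G0_draws, C0_draws, R0_draws, 1
    if not _inv_spd(C0, L, C0inv):
        return G0_draws, C0_draws, R0_draws, 1
    if not _inv_spd(R0, L, R0inv):
        return G0_draws, C0_draws, R0_draws, 1

    # residuals; missing cells start at their fitted value (e = 0)
    e = np.empty((n, t))
    for i in range(n):
        for m in range(t):
            fit = a[rec_animal[i], m] + c[rec_pen[i], m]
            for j in range(p):
                fit += X[i, j] * b[j, m]
            if miss[i, m] == 1:
                y[i, m] = fit
                e[i, m] = 0.0
            else:
                e[i, m] = y[i, m] - fit

    isave = 0
    for it in range(n_iter):
        if sample_location == 1:
            # --- missing-trait augmentation (bivariate only in practice)
            if t == 2:
                for i in range(n):
                    if miss[i, 0] == 1 or miss[i, 1] == 1:
                        if miss[i, 0] == 1 and miss[i, 1] == 1:
                            # both missing: draw e ~ N(0, R0)
                            if not _chol(R0, L):
                                return G0_draws, C0_draws, R0_draws, 1 + it
                            z0 = np.random.standard_normal()
                            z1 = np.random.standard_normal()
                            e[i, 0] = L[0, 0] * z0
                            e[i, 1] = L[1, 0] * z0 + L[1, 1] * z1
                        else:
                            mm = 0 if miss[i, 0] == 1 else 1
                            o = 1 - mm
                            cmean = R0[mm, o] / R0[o, o] * e[i, o]
                            cvar = R0[mm, mm] - R0[mm, o] ** 2 / R0[o, o]
                            if cvar <= 0.0:
                                return G0_draws, C0_draws, R0_draws, 1 + it
                            e[i, mm] = cmean + np.sqrt(cvar) * np.random.standard_normal()
                        for m in range(t):
                            if miss[i, m] == 1:
                                fit = a[rec_animal[i], m] + c[rec_pen[i], m]
                                for j in range(p):
                                    fit += X[i, j] * b[j, m]
                                y[i, m] = fit + e[i, m]

            # --- fixed effects, column by column
            for j in range(p):
                for m in range(t):
                    sv[m] = 0.0
                for i in range(n):
                    xij = X[i, j]
                    if xij != 0.0:
                        for m in range(t):
                            e[i, m] += xij * b[j, m]
                            sv[m] += xij * e[i, m]
                for m in range(t):
                    rhs[m] = 0.0
                    for l in range(t):
                        rhs[m] += R0inv[m, l] * sv[l]
                    for l in range(t):
                        P[m, l] = sxx[j] * R0inv[m, l]
                if not _draw_mvn_prec(P, rhs, L, w, out):
                    return G0_draws, C0_draws, R0_draws, 1 + it
                for m in range(t):
                    b[j, m] = out[m]
                for i in range(n):
                    xij = X[i, j]
                    if xij != 0.0:
                        for m in range(t):
                            e[i, m] -= xij * b[j, m]

            # --- breeding values, animal by animal over the whole pedigree
            for i in range(q):
                dii = 0.0
                for m in range(t):
                    sv[m] = 0.0
                for kk in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    jj = ainv_indices[kk]
                    val = ainv_data[kk]
                    if jj == i:
                        dii = val
                    else:
                        for m in range(t):
                            sv[m] += val * a[jj, m]
                r = rec_of_animal[i]
                for m in range(t):
                    rhs[m] = 0.0
                    for l in range(t):
                        rhs[m] -= G0inv[m, l] * sv[l]
                    for l in range(t):
                        P[m, l] = dii * G0inv[m, l]
                if r >= 0:
                    for m in range(t):
                        e[r, m] += a[i, m]
                    for m in range(t):
                        for l in range(t):
                            rhs[m] += R0inv[m, l] * e[r, l]
                            P[m, l] += R0inv[m, l]
                if not _draw_mvn_prec(P, rhs, L, w, out):
                    return G0_draws, C0_draws, R0_draws, 1 + it
                for m in range(t):
                    a[i, m] = out[m]
                if r >= 0:
                    for m in range(t):
                        e[r, m] -= a[i, m]

            # --- pen effects
            for k in range(npen):
                nk = pen_indptr[k + 1] - pen_indptr[k]
                for m in range(t):
                    sv[m] = 0.0
                for kk in range(pen_indptr[k], pen_indptr[k + 1]):
                    r = pen_records[kk]
                    for m in range(t):
                        e[r, m] += c[k, m]
                        sv[m] += e[r, m]
                for m in range(t):
                    rhs[m] = 0.0
                    for l in range(t):
                        rhs[m] += R0inv[m, l] * sv[l]
                    for l in range(t):
                        P[m, l] = nk * R0inv[m, l] + C0inv[m, l]
                if not _draw_mvn_prec(P, rhs, L, w, out):
                    return G0_draws, C0_draws, R0_draws, 1 + it
                for m in range(t):
                    c[k, m] = out[m]
                for kk in range(pen_indptr[k], pen_indptr[k + 1]):
                    r = pen_records[kk]
                    for m in range(t):
                        e[r, m] -= c[k, m]

        # --- quadratic forms
        for i in range(q):
            for m in range(t):
                s = 0.0
                for kk in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    s += ainv_data[kk] * a[ainv_indices[kk], m]
                u[i, m] = s
        for m in range(t):
            for l in range(t):
                s = 0.0
                for i in range(q):
                    s += a[i, m] * u[i, l]
                Sa[m, l] = s + Sg[m, l]
                s = 0.0
                for k in range(npen):
                    s += c[k, m] * c[k, l]
                Sc[m, l] = s + Sc_prior[m, l]
                s = 0.0
                for i in range(n):
                    s += e[i, m] * e[i, l]
                Se[m, l] = s + Sr[m, l]

        # --- variance components from inverse-Wishart conditionals
        if not _draw_invwishart(Sa, nu_g + q, G0):
            return G0_draws, C0_draws, R0_draws, 1 + it
        if not _draw_invwishart(Sc, nu_c + npen, C0):
            return G0_draws, C0_draws, R0_draws, 1 + it
        if not _draw_invwishart(Se, nu_r + n, R0):
            return G0_draws, C0_draws, R0_draws, 1 + it
        if not _inv_spd(G0, L, G0inv):
            return G0_draws, C0_draws, R0_draws, 1 + it
        if not _inv_spd(C0, L, C0inv):
            return G0_draws, C0_draws, R0_draws, 1 + it
        if not _inv_spd(R0, L, R0inv):
            return G0_draws, C0_draws, R0_draws, 1 + it

        if it >= burn_in and (it - burn_in) % thin == 0:
            for m in range(t):
                for l in range(t):
                    G0_draws[isave, m, l] = G0[m, l]
                    C0_draws[isave, m, l] = C0[m, l]
                    R0_draws[isave, m, l] = R0[m, l]
            isave += 1

    return G0_draws, C0_draws, R0_draws, 0
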