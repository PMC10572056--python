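"""Numba-compiled Gibbs kernels for the marker-effect samplers.

Both kernels run the classic single-site (coordinate) Gibbs scheme on the
model

    y = X b + W d + M alpha + e

with a flat prior on the fixed effects b, i.i.d. normal days-in-milk class
effects d, i.i.d. normal marker effects alpha (a t-variate normal per marker
in the multi-trait kernel) and scaled-inverse-chi-square / inverse-Wishart
priors on the variance components.  A running residual vector/matrix is
maintained so each marker update costs O(n) (O(n t + t^3) multi-trait).

All randomness flows through numba's own np.random state, seeded once at
kernel entry, which makes every chain bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_lower(A, L):
    """In-place lower Cholesky of A into L; returns False if not PD."""
    t = A.shape[0]
    for i in range(t):
        for j in range(t):
            L[i, j] = 0.0
    for i in range(t):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _solve_chol(L, b, x):
    """Solve (L L') x = b given lower Cholesky L."""
    t = L.shape[0]
    for i in range(t):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(t - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, t):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _solve_upperT(L, z, x):
    """Solve L' x = z (L lower): adds N(0, (L L')^-1) noise when z ~ N(0, I)."""
    t = L.shape[0]
    for i in range(t - 1, -1, -1):
        s = z[i]
        for k in range(i + 1, t):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _inv_pd(A, out, scratch):
    """Invert a symmetric PD matrix via Cholesky; returns False on failure."""
    t = A.shape[0]
    ok = _chol_lower(A, scratch)
    if not ok:
        return False
    e = np.zeros(t)
    x = np.zeros(t)
    for j in range(t):
        for i in range(t):
            e[i] = 1.0 if i == j else 0.0
        _solve_chol(scratch, e, x)
        for i in range(t):
            out[i, j] = x[i]
    for i in range(t):
        for j in range(i):
            m = 0.5 * (out[i, j] + out[j, i])
            out[i, j] = m
            out[j, i] = m
    return True


@njit(cache=True)
def _inv_wishart(df, S, out):
    """Draw out ~ InvWishart(df, S) by Bartlett; returns False on failure.

    Parameterized so that E[out] = S / (df - t - 1) for df > t + 1.
    """
    t = S.shape[0]
    Sinv = np.zeros((t, t))
    scratch = np.zeros((t, t))
    if not _inv_pd(S, Sinv, scratch):
        return False
    L = np.zeros((t, t))
    if not _chol_lower(Sinv, L):
        return False
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    # W = (L A)(L A)' ~ Wishart(df, Sinv); out = W^-1
    LA = L @ A
    W = LA @ LA.T
    Winv = np.zeros((t, t))
    if not _inv_pd(W, Winv, scratch):
        return False
    for i in range(t):
        for j in range(t):
            out[i, j] = Winv[i, j]
    return True


@njit(cache=True)
def st_chain(
    y,
    X,
    dim_class,
    n_dim,
    Mt,
    n_iter,
    burn_in,
    thin,
    nu_a,
    S_a,
    nu_d,
    S_d,
    nu_e,
    S_e,
    s2a0,
    s2d0,
    s2e0,
    sample_s2a,
    sample_s2d,
    sample_s2e,
    seed,
):
    """Single-trait Gibbs chain.  Mt is the (p, n) transposed centered marker matrix.

    Returns (alpha_draws, b_draws, d_draws, s2a_draws, s2d_draws, s2e_draws,
    status) where status 0 means success and 1 flags a non-finite state
    (the failing iteration is recoverable from the wrapper's error message).
    """
    np.random.seed(seed)
    p, n = Mt.shape
    f = X.shape[1]
    n_keep = (n_iter - burn_in) // thin

    mtm = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Mt[j, i] * Mt[j, i]
        mtm[j] = s

    XtX = X.T @ X
    Lx = np.linalg.cholesky(XtX)

    class_count = np.zeros(n_dim)
    for i in range(n):
        if n_dim > 0:
            class_count[dim_class[i]] += 1.0

    b = np.zeros(f)
    d = np.zeros(n_dim)
    alpha = np.zeros(p)
    s2a = s2a0
    s2d = s2d0
    s2e = s2e0

    e = y.copy()

    alpha_draws = np.zeros((n_keep, p))
    b_draws = np.zeros((n_keep, f))
    d_draws = np.zeros((n_keep, n_dim))
    s2a_draws = np.zeros(n_keep)
    s2d_draws = np.zeros(n_keep)
    s2e_draws = np.zeros(n_keep)

    status = 0
    fail_iter = -1
    kept = 0
    zf = np.zeros(f)
    bnew = np.zeros(f)

    for it in range(1, n_iter + 1):
        # --- fixed effects: flat prior, joint multivariate-normal draw
        yb = e + X @ b
        rhs = X.T @ yb
        bhat = np.linalg.solve(XtX, rhs)
        for k in range(f):
            zf[k] = np.random.standard_normal()
        _solve_upperT(Lx, zf, bnew)
        for k in range(f):
            bnew[k] = bhat[k] + np.sqrt(s2e) * bnew[k]
        e = yb - X @ bnew
        for k in range(f):
            b[k] = bnew[k]

        # --- DIM class effects
        if n_dim > 0:
            csum = np.zeros(n_dim)
            for i in range(n):
                csum[dim_class[i]] += e[i]
            for l in range(n_dim):
                full = csum[l] + class_count[l] * d[l]
                prec = class_count[l] / s2e + 1.0 / s2d
                mean = (full / s2e) / prec
                dnew = mean + np.random.standard_normal() / np.sqrt(prec)
                delta = dnew - d[l]
                d[l] = dnew
                csum[l] = 0.0
                if delta != 0.0:
                    for i in range(n):
                        if dim_class[i] == l:
                            e[i] -= delta

        # --- marker effects, single-site
        for j in range(p):
            dot = 0.0
            for i in range(n):
                dot += Mt[j, i] * e[i]
            full = dot + mtm[j] * alpha[j]
            prec = mtm[j] / s2e + 1.0 / s2a
            mean = (full / s2e) / prec
            anew = mean + np.random.standard_normal() / np.sqrt(prec)
            delta = anew - alpha[j]
            alpha[j] = anew
            for i in range(n):
                e[i] -= Mt[j, i] * delta

        # --- variance components (scaled inverse chi-square)
        if sample_s2a:
            ssa = 0.0
            for j in range(p):
                ssa += alpha[j] * alpha[j]
            s2a = (nu_a * S_a + ssa) / np.random.chisquare(nu_a + p)
        if sample_s2d and n_dim > 0:
            ssd = 0.0
            for l in range(n_dim):
                ssd += d[l] * d[l]
            s2d = (nu_d * S_d + ssd) / np.random.chisquare(nu_d + n_dim)
        if sample_s2e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)

        if not (np.isfinite(s2a) and np.isfinite(s2e) and np.isfinite(s2d)):
            status = 1
            fail_iter = it
            break

        if it > burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            alpha_draws[kept] = alpha
            b_draws[kept] = b
            if n_dim > 0:
                d_draws[kept] = d
            s2a_draws[kept] = s2a
            s2d_draws[kept] = s2d
            s2e_draws[kept] = s2e
            kept += 1

    return (
        alpha_draws,
        b_draws,
        d_draws,
        s2a_draws,
        s2d_draws,
        s2e_draws,
        status,
        fail_iter,
    )


@njit(cache=True)
def mt_chain(
    Y,
    X,
    dim_class,
    n_dim,
    Mt,
    n_iter,
    burn_in,
    thin,
    nu_a,
    S_a,
    nu_d,
    S_d_diag,
    nu_e,
    S_e,
    Sa0,
    s2d0,
    R0,
    sample_Sa,
    sample_s2d,
    sample_R,
    seed,
):
    """Multi-trait Gibbs chain with per-marker t-variate effect vectors.

    The genetic values inherit the Kronecker covariance Sigma (x) K from the
    i.i.d. per-marker effect vectors a_j ~ N(0, Sigma_alpha); residual rows
    are N(0, R).  Days-in-milk class effects use a diagonal across-trait
    covariance diag(s2d).
    """
    np.random.seed(seed)
    p, n = Mt.shape
    t = Y.shape[1]
    f = X.shape[1]
    n_keep = (n_iter - burn_in) // thin

    mtm = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Mt[j, i] * Mt[j, i]
        mtm[j] = s

    XtX = X.T @ X
    Lx = np.linalg.cholesky(XtX)

    class_count = np.zeros(n_dim)
    for i in range(n):
        if n_dim > 0:
            class_count[dim_class[i]] += 1.0

    B = np.zeros((f, t))
    D = np.zeros((n_dim, t))
    A = np.zeros((p, t))
    Sa = Sa0.copy()
    R = R0.copy()
    s2d = s2d0.copy()

    E = Y.copy()

    alpha_draws = np.zeros((n_keep, p, t))
    b_draws = np.zeros((n_keep, f, t))
    d_draws = np.zeros((n_keep, n_dim, t))
    Sa_draws = np.zeros((n_keep, t, t))
    R_draws = np.zeros((n_keep, t, t))
    s2d_draws = np.zeros((n_keep, t))

    Rinv = np.zeros((t, t))
    Sainv = np.zeros((t, t))
    scratch = np.zeros((t, t))
    C = np.zeros((t, t))
    Lc = np.zeros((t, t))
    sv = np.zeros(t)
    rhs = np.zeros(t)
    mean = np.zeros(t)
    zt = np.zeros(t)
    noise = np.zeros(t)
    LR = np.zeros((t, t))

    status = 0
    fail_iter = -1
    kept = 0

    for it in range(1, n_iter + 1):
        if not _inv_pd(R, Rinv, scratch):
            status = 2
            fail_iter = it
            break
        if not _inv_pd(Sa, Sainv, scratch):
            status = 2
            fail_iter = it
            break
        if not _chol_lower(R, LR):
            status = 2
            fail_iter = it
            break

        # --- fixed effects: matrix-normal draw MN(Bhat, (X'X)^-1, R)
        Yb = E + X @ B
        Bhat = np.linalg.solve(XtX, X.T @ Yb)
        Z = np.zeros((f, t))
        for a_ in range(f):
            for c_ in range(t):
                Z[a_, c_] = np.random.standard_normal()
        Znoise = np.zeros((f, t))
        col = np.zeros(f)
        out = np.zeros(f)
        for c_ in range(t):
            for a_ in range(f):
                col[a_] = Z[a_, c_]
            _solve_upperT(Lx, col, out)
            for a_ in range(f):
                Znoise[a_, c_] = out[a_]
        Bnew = Bhat + Znoise @ LR.T
        E = Yb - X @ Bnew
        B = Bnew

        # --- DIM class effects: t-vector per class, diagonal prior
        if n_dim > 0:
            csum = np.zeros((n_dim, t))
            for i in range(n):
                l = dim_class[i]
                for c_ in range(t):
                    csum[l, c_] += E[i, c_]
            for l in range(n_dim):
                for c_ in range(t):
                    sv[c_] = csum[l, c_] + class_count[l] * D[l, c_]
                for a_ in range(t):
                    acc = 0.0
                    for c_ in range(t):
                        C[a_, c_] = class_count[l] * Rinv[a_, c_]
                        acc += Rinv[a_, c_] * sv[c_]
                    rhs[a_] = acc
                    C[a_, a_] += 1.0 / s2d[a_]
                if not _chol_lower(C, Lc):
                    status = 2
                    fail_iter = it
                    break
                _solve_chol(Lc, rhs, mean)
                for c_ in range(t):
                    zt[c_] = np.random.standard_normal()
                _solve_upperT(Lc, zt, noise)
                for c_ in range(t):
                    dnew = mean[c_] + noise[c_]
                    delta = dnew - D[l, c_]
                    D[l, c_] = dnew
                    if delta != 0.0:
                        for i in range(n):
                            if dim_class[i] == l:
                                E[i, c_] -= delta
            if status != 0:
                break

        # --- marker effect vectors, single-site
        for j in range(p):
            for c_ in range(t):
                acc = 0.0
                for i in range(n):
                    acc += Mt[j, i] * E[i, c_]
                sv[c_] = acc + mtm[j] * A[j, c_]
            for a_ in range(t):
                acc = 0.0
                for c_ in range(t):
                    C[a_, c_] = mtm[j] * Rinv[a_, c_] + Sainv[a_, c_]
                    acc += Rinv[a_, c_] * sv[c_]
                rhs[a_] = acc
            if not _chol_lower(C, Lc):
                status = 2
                fail_iter = it
                break
            _solve_chol(Lc, rhs, mean)
            for c_ in range(t):
                zt[c_] = np.random.standard_normal()
            _solve_upperT(Lc, zt, noise)
            for c_ in range(t):
                anew = mean[c_] + noise[c_]
                delta = anew - A[j, c_]
                A[j, c_] = anew
                if delta != 0.0:
                    for i in range(n):
                        E[i, c_] -= Mt[j, i] * delta
        if status != 0:
            break

        # --- covariance components
        if sample_Sa:
            Spost = S_a + A.T @ A
            ok = _inv_wishart(nu_a + p, Spost, Sa)
            if not ok:
                # jitter-and-retry once on the posterior scale matrix
                for c_ in range(t):
                    Spost[c_, c_] += 1e-8 * Spost[c_, c_] + 1e-12
                ok = _inv_wishart(nu_a + p, Spost, Sa)
                if not ok:
                    status = 3
                    fail_iter = it
                    break
        if sample_s2d and n_dim > 0:
            for c_ in range(t):
                ssd = 0.0
                for l in range(n_dim):
                    ssd += D[l, c_] * D[l, c_]
                s2d[c_] = (nu_d * S_d_diag[c_] + ssd) / np.random.chisquare(
                    nu_d + n_dim
                )
        if sample_R:
            Spost = S_e + E.T @ E
            ok = _inv_wishart(nu_e + n, Spost, R)
            if not ok:
                for c_ in range(t):
                    Spost[c_, c_] += 1e-8 * Spost[c_, c_] + 1e-12
                ok = _inv_wishart(nu_e + n, Spost, R)
                if not ok:
                    status = 3
                    fail_iter = it
                    break

        finite = True
        for a_ in range(t):
            if not (np.isfinite(Sa[a_, a_]) and np.isfinite(R[a_, a_])):
                finite = False
        if not finite:
            status = 1
            fail_iter = it
            break

        if it > burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            alpha_draws[kept] = A
            b_draws[kept] = B
            if n_dim > 0:
                d_draws[kept] = D
            Sa_draws[kept] = Sa
            R_draws[kept] = R
            s2d_draws[kept] = s2d
            kept += 1

    return (
        alpha_draws,
        b_draws,
        d_draws,
        Sa_draws,
        R_draws,
        s2d_draws,
        status,
        fail_iter,
    )
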