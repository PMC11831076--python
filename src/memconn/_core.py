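"""Compiled inner loops for relevance vector regression.

The evidence-maximization iteration is O(a^3) per step (a = active basis
count) and the cross-validated permutation machinery runs it hundreds of
thousands of times, so the loop lives here as numba-compiled kernels.
``memconn.rvr`` wraps these in the public API; the algorithm itself is the
standard (non-"fast") sparse-Bayes iteration:

    Sigma = (A + sigma^-2 Phi' Phi)^-1          posterior covariance
    mu    = sigma^-2 Sigma Phi' y               posterior mean
    gamma_i = 1 - alpha_i Sigma_ii              well-determinedness
    alpha_i <- gamma_i / mu_i^2                 MacKay update
    sigma^2 <- ||y - Phi mu||^2 / (n - sum gamma)

Basis columns whose alpha exceeds the prune threshold are removed; the
survivors index the relevance vectors.  Column 0 of Phi is the bias and,
by default, carries alpha = 0 (an unpenalized, improper flat prior); it is
never pruned in that mode.  H = A + sigma^-2 Phi'Phi is positive definite
whenever at most one alpha is zero, so each step factorizes H = L L' with
a hand-rolled contiguous-access Cholesky and only the posterior mean, the
Sigma diagonal and log|H| are ever materialized — never a full inverse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = 1.8378770664093453


@njit(cache=True, fastmath=True)
def _chol_lower(H):
    """Cholesky factor of a PD matrix, row-contiguous inner loops."""
    a = H.shape[0]
    L = np.zeros((a, a))
    for j in range(a):
        s = H[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s < 1e-30:
            s = 1e-30
        d = np.sqrt(s)
        L[j, j] = d
        for i in range(j + 1, a):
            t = H[i, j]
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t / d
    return L


@njit(cache=True, fastmath=True)
def _chol_of_posterior(PtP, alpha, inv_s2):
    """Cholesky factor of H = PtP * inv_s2 + diag(alpha), built in place.

    Pivots are floored relative to the largest diagonal entry: near the
    interpolation limit (sigma^2 at its floor) H is numerically singular,
    and an absolute guard would emit garbage-scale factors; the relative
    guard acts as the smallest jitter that keeps the solve bounded.
    """
    a = PtP.shape[0]
    hmax = 1e-300
    for j in range(a):
        hj = PtP[j, j] * inv_s2 + alpha[j]
        if hj > hmax:
            hmax = hj
    floor = 1e-13 * hmax
    L = np.zeros((a, a))
    for j in range(a):
        s = PtP[j, j] * inv_s2 + alpha[j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s < floor:
            s = floor
        d = np.sqrt(s)
        L[j, j] = d
        for i in range(j + 1, a):
            t = PtP[i, j] * inv_s2
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t / d
    return L


@njit(cache=True, fastmath=True)
def _sigma_diag(L):
    """diag(H^-1) from the Cholesky factor via a transposed L^-1.

    Columns of L^-1 are built in pairs to halve loop overhead;
    LinvT[j, i] = (L^-1)[i, j], so rows of LinvT (columns of L^-1) are
    contiguous in the inner loops.
    """
    a = L.shape[0]
    LinvT = np.zeros((a, a))
    j = 0
    while j + 1 < a:
        LinvT[j, j] = 1.0 / L[j, j]
        LinvT[j, j + 1] = -L[j + 1, j] * LinvT[j, j] / L[j + 1, j + 1]
        LinvT[j + 1, j + 1] = 1.0 / L[j + 1, j + 1]
        for i in range(j + 2, a):
            s0 = 0.0
            s1 = 0.0
            for k in range(j, i):
                lik = L[i, k]
                s0 -= lik * LinvT[j, k]
                s1 -= lik * LinvT[j + 1, k]
            LinvT[j, i] = s0 / L[i, i]
            LinvT[j + 1, i] = s1 / L[i, i]
        j += 2
    if j < a:
        LinvT[j, j] = 1.0 / L[j, j]
        for i in range(j + 1, a):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * LinvT[j, k]
            LinvT[j, i] = s / L[i, i]
    sig = np.empty(a)
    for i in range(a):
        s = 0.0
        for k in range(i, a):
            s += LinvT[i, k] * LinvT[i, k]
        sig[i] = s
    return sig


@njit(cache=True, fastmath=True)
def _solve_mu(L, b):
    """Solve (L L') mu = b by forward and back substitution."""
    a = L.shape[0]
    u = np.empty(a)
    for i in range(a):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * u[k]
        u[i] = s / L[i, i]
    mu = np.empty(a)
    for i in range(a - 1, -1, -1):
        s = u[i]
        for k in range(i + 1, a):
            s -= L[k, i] * mu[k]
        mu[i] = s / L[i, i]
    return mu


@njit(cache=True, fastmath=True)
def rvr_fit_core(
    PhiTPhi,
    PhiTy,
    Phi,
    y,
    alpha_init,
    sigma2_init,
    bias_unpenalized,
    update_hyperparameters,
    max_iter,
    tol,
    prune_threshold,
    sigma2_floor,
    compute_evidence,
    evidence_bias_alpha,
):
    """Run evidence maximization; return the full-length posterior summary.

    Returns (mu_full, active, alpha, sigma2, n_iter, converged, evidence)
    where mu_full has one entry per Phi column (zeros where pruned).  The
    active basis is kept in compact contiguous arrays that are rebuilt
    only when a column is pruned.
    """
    n = y.shape[0]
    M = PhiTPhi.shape[0]
    alpha_full = np.full(M, alpha_init)
    if bias_unpenalized:
        alpha_full[0] = 0.0
    active = np.ones(M, np.bool_)
    cols = np.arange(M)
    PtP_c = PhiTPhi.copy()
    b_c = PhiTy.copy()
    alpha_c = alpha_full.copy()
    sigma2 = sigma2_init
    evidence = np.full(max_iter, np.nan)
    converged = False
    n_iter = 0
    yTy = 0.0
    for t in range(n):
        yTy += y[t] * y[t]
    prev_d_s2 = 0.0
    cooldown = 0
    # stagnation detector: MacKay iterations can fall into a limit cycle
    # (alpha and sigma^2 oscillating above tol forever); if max |dlog alpha|
    # sets no new minimum for a full window, stop and flag non-convergence
    # instead of burning the whole iteration budget inside the cycle.
    best_dlog = np.inf
    stall = 0

    for it in range(max_iter):
        n_iter = it + 1
        a = cols.shape[0]
        if a == 0:
            converged = True
            break
        inv_s2 = 1.0 / sigma2
        L = _chol_of_posterior(PtP_c, alpha_c, inv_s2)
        sig_diag = _sigma_diag(L)
        bb = np.empty(a)
        for i in range(a):
            bb[i] = b_c[i] * inv_s2
        mu = _solve_mu(L, bb)

        # ||y - Phi mu||^2 in O(a): H mu = Phi'y/sigma^2 exactly, so
        # mu'Phi'Phi mu = mu'b - sigma^2 sum_i alpha_i mu_i^2 and
        # rss = y'y - mu'b - sigma^2 sum_i alpha_i mu_i^2.
        mu_b = 0.0
        mu_a_mu = 0.0
        for i in range(a):
            mu_b += mu[i] * b_c[i]
            mu_a_mu += alpha_c[i] * mu[i] * mu[i]
        rss = yTy - mu_b - sigma2 * mu_a_mu
        if rss < 0.0:
            rss = 0.0
        sum_gamma = 0.0
        for i in range(a):
            g = 1.0 - alpha_c[i] * sig_diag[i]
            if g < 0.0:
                g = 0.0
            elif g > 1.0:
                g = 1.0
            sum_gamma += g

        if compute_evidence:
            # log marginal likelihood via the determinant identity
            # |C| = sigma^2n |A|^-1 |H|;  y'C^-1 y = (y'y - Phi'y . mu)/sigma^2
            logdetH = 0.0
            for i in range(a):
                logdetH += 2.0 * np.log(L[i, i])
            logdetA = 0.0
            for i in range(a):
                av = alpha_c[i]
                if av <= 0.0:
                    av = evidence_bias_alpha
                logdetA += np.log(av)
            quad = (yTy - mu_b) / sigma2
            logdetC = n * np.log(sigma2) - logdetA + logdetH
            evidence[it] = -0.5 * (n * _LOG_2PI + logdetC + quad)

        if not update_hyperparameters:
            converged = True
            break

        # MacKay updates with pruning.  Pruned columns are tracked with an
        # explicit mask (no inf sentinel inside this fastmath function).
        max_dlog = 0.0
        n_pruned = 0
        drop = np.zeros(a, np.bool_)
        for i in range(a):
            k = cols[i]
            if bias_unpenalized and k == 0:
                continue
            g = 1.0 - alpha_c[i] * sig_diag[i]
            if g < 1e-12:
                g = 1e-12
            elif g > 1.0:
                g = 1.0
            mu2 = mu[i] * mu[i]
            if mu2 < 1e-300:
                new_a = prune_threshold * 10.0
            else:
                new_a = g / mu2
            if new_a > prune_threshold:
                active[k] = False
                alpha_full[k] = np.inf
                drop[i] = True
                n_pruned += 1
            else:
                d = np.abs(np.log(new_a) - np.log(alpha_c[i]))
                if d > max_dlog:
                    max_dlog = d
                alpha_c[i] = new_a
                alpha_full[k] = new_a
        denom = n - sum_gamma
        if denom < 1e-10:
            denom = 1e-10
        new_s2 = rss / denom
        if new_s2 < sigma2_floor:
            new_s2 = sigma2_floor
        # The noise variance approaches its fixed point geometrically and
        # can take hundreds of iterations on ill-conditioned kernels.  When
        # consecutive log-sigma^2 steps show a stable geometric ratio,
        # Aitken-extrapolate to the predicted limit (guarded, with a
        # cooldown so transients settle).  The fixed point is unchanged;
        # only the approach to it is shortened.
        d_s2 = np.log(new_s2) - np.log(sigma2)
        sigma2 = new_s2
        if cooldown > 0:
            cooldown -= 1
        elif prev_d_s2 > 0.0 and d_s2 > 1e-5:
            # upward recoveries only: extrapolating a downward crash would
            # drive sigma^2 to the floor and destroy the conditioning of H
            rho = d_s2 / prev_d_s2
            if 0.5 < rho < 0.999:
                jump = d_s2 * rho / (1.0 - rho)
                if jump > 6.9:
                    jump = 6.9
                elif jump < -6.9:
                    jump = -6.9
                sigma2 = sigma2 * np.exp(jump)
                if sigma2 < sigma2_floor:
                    sigma2 = sigma2_floor
                cooldown = 5
                d_s2 = 0.0
        prev_d_s2 = d_s2

        if n_pruned > 0:
            keep = np.flatnonzero(~drop)
            na = keep.shape[0]
            new_PtP = np.empty((na, na))
            for i in range(na):
                ki = keep[i]
                for j in range(na):
                    new_PtP[i, j] = PtP_c[ki, keep[j]]
            new_b = np.empty(na)
            new_alpha = np.empty(na)
            new_cols = np.empty(na, cols.dtype)
            for i in range(na):
                ki = keep[i]
                new_b[i] = b_c[ki]
                new_alpha[i] = alpha_c[ki]
                new_cols[i] = cols[ki]
            PtP_c = new_PtP
            b_c = new_b
            alpha_c = new_alpha
            cols = new_cols
        elif max_dlog < tol:
            converged = True
            break
        if n_pruned == 0:
            if max_dlog < best_dlog * 0.999:
                best_dlog = max_dlog
                stall = 0
            else:
                stall += 1
                if stall >= 40 and it >= 20:
                    break
        else:
            best_dlog = np.inf
            stall = 0

    # final posterior under the final hyperparameters
    mu_full = np.zeros(M)
    a = cols.shape[0]
    if a > 0:
        inv_s2 = 1.0 / sigma2
        L = _chol_of_posterior(PtP_c, alpha_c, inv_s2)
        bb = np.empty(a)
        for i in range(a):
            bb[i] = b_c[i] * inv_s2
        mu = _solve_mu(L, bb)
        for i in range(a):
            mu_full[cols[i]] = mu[i]
    return mu_full, active, alpha_full, sigma2, n_iter, converged, evidence[:n_iter]


@njit(cache=True, fastmath=True)
def rvr_fit_predict_batch(
    Phi_tr,
    Phi_te,
    Y,
    alpha_init,
    sigma2_init_scale,
    bias_unpenalized,
    max_iter,
    tol,
    prune_threshold,
    sigma2_floor,
):
    """Fit one design against many target vectors and predict held-out rows.

    ``Y`` is n_train x P (one column per permutation / replicate); the
    initial noise variance is ``sigma2_init_scale`` times each column's
    variance.  Returns (preds: n_test x P, converged: P bools).
    """
    n_tr = Phi_tr.shape[0]
    M = Phi_tr.shape[1]
    P = Y.shape[1]
    n_te = Phi_te.shape[0]
    PhiTPhi = Phi_tr.T @ Phi_tr
    preds = np.empty((n_te, P))
    conv = np.empty(P, np.bool_)
    for c in range(P):
        y = Y[:, c].copy()
        mean = 0.0
        for t in range(n_tr):
            mean += y[t]
        mean /= n_tr
        var = 0.0
        for t in range(n_tr):
            d = y[t] - mean
            var += d * d
        var /= n_tr
        s2 = sigma2_init_scale * var
        if s2 < sigma2_floor:
            s2 = sigma2_floor
        PhiTy = Phi_tr.T @ y
        mu_full, active, alpha, sigma2, n_iter, converged, _ = rvr_fit_core(
            PhiTPhi,
            PhiTy,
            Phi_tr,
            y,
            alpha_init,
            s2,
            bias_unpenalized,
            True,
            max_iter,
            tol,
            prune_threshold,
            sigma2_floor,
            False,
            1.0,
        )
        conv[c] = converged
        for t in range(n_te):
            s = 0.0
            for k in range(M):
                s += Phi_te[t, k] * mu_full[k]
            preds[t, c] = s
    return preds, conv
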