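"""Numba kernel for blocked single-site Gibbs updates of location effects.

One call updates every level of one effect group from its full
conditional. Levels are k-dimensional coefficient blocks; the conditional
precision is (sum_r x_r x_r')/sigma_e2 plus the prior precision, which for
the additive-genetic group couples an animal to its pedigree neighbours
through the sparse A-inverse. All randomness enters through the ``z``
array of standard normals drawn by the caller, so chains are reproducible
from a single numpy Generator.
"""
import numpy as np
from numba import njit

__all__ = ["sample_group", "resample_additive_pe_split"]


@njit(cache=True, inline="always")
def _cholesky(P, Lc, k):
    for i in range(k):
        for j in range(i + 1):
            s = P[i, j]
            for m in range(j):
                s -= Lc[i, m] * Lc[j, m]
            if i == j:
                Lc[i, i] = np.sqrt(s)
            else:
                Lc[i, j] = s / Lc[j, j]


@njit(cache=True)
def resample_additive_pe_split(cow_anim, a, p, Ginv, Rpinv, z,
                               ainv_indptr, ainv_indices, ainv_data):
    """Interweaving sweep for the additive / permanent-environment split.

    For every cow with records, the likelihood depends on a_i + p_i only
    (Z and W share covariates), so conditional on s_i = a_i + p_i the
    split is a prior-only Gaussian: precision A^-1_ii G0^-1 + Rp^-1, mean
    from the pedigree neighbours and Rp^-1 s_i. Re-sampling it directly
    decouples the G0/Rp scales from the slow data-sweep random walk.

    cow_anim: (n_cows,) animal index of each PE level; a: (n_animals, k)
    and p: (n_cows, k) updated in place; z: (n_cows, k) standard normals.
    """
    n_cows, k = p.shape
    P = np.zeros((k, k))
    Lc = np.zeros((k, k))
    r = np.zeros(k)
    u = np.zeros(k)
    mu = np.zeros(k)
    w = np.zeros(k)
    svec = np.zeros(k)
    for c in range(n_cows):
        i = cow_anim[c]
        dii = 0.0
        for a_ in range(k):
            svec[a_] = 0.0
        for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
            j = ainv_indices[ptr]
            v = ainv_data[ptr]
            if j == i:
                dii = v
            else:
                for a_ in range(k):
                    svec[a_] += v * a[j, a_]
        for a_ in range(k):
            r[a_] = 0.0
            for b in range(k):
                P[a_, b] = dii * Ginv[a_, b] + Rpinv[a_, b]
                r[a_] -= Ginv[a_, b] * svec[b]
                r[a_] += Rpinv[a_, b] * (a[i, b] + p[c, b])
        _cholesky(P, Lc, k)
        for ii in range(k):
            s = r[ii]
            for m in range(ii):
                s -= Lc[ii, m] * u[m]
            u[ii] = s / Lc[ii, ii]
        for ii in range(k - 1, -1, -1):
            s = u[ii]
            for m in range(ii + 1, k):
                s -= Lc[m, ii] * mu[m]
            mu[ii] = s / Lc[ii, ii]
        for ii in range(k - 1, -1, -1):
            s = z[c, ii]
            for m in range(ii + 1, k):
                s -= Lc[m, ii] * w[m]
            w[ii] = s / Lc[ii, ii]
        for a_ in range(k):
            s_tot = a[i, a_] + p[c, a_]
            a_new = mu[a_] + w[a_]
            a[i, a_] = a_new
            p[c, a_] = s_tot - a_new


@njit(cache=True)
def sample_group(level_ptr, rec_order, rec_cov, e, sig2e, theta, Qp, z,
                 ainv_indptr, ainv_indices, ainv_data, use_ped):
    """Gibbs-update all levels of one effect group in place.

    level_ptr/rec_order: CSR mapping level -> record indices.
    rec_cov: (n_records, k) covariates in record order.
    e: residual vector, kept consistent incrementally.
    theta: (n_levels, k) current coefficients, updated in place.
    Qp: (k, k) prior precision of one level (for the pedigree group this
        is G0^-1 and is scaled/coupled by the A-inverse CSR arrays).
    z: (n_levels, k) standard normals.
    """
    n_levels, k = theta.shape
    P = np.zeros((k, k))
    Lc = np.zeros((k, k))
    r = np.zeros(k)
    u = np.zeros(k)
    mu = np.zeros(k)
    w = np.zeros(k)
    svec = np.zeros(k)
    inv_s = 1.0 / sig2e
    for lev in range(n_levels):
        for a in range(k):
            r[a] = 0.0
            for b in range(k):
                P[a, b] = 0.0
        # data contribution
        for t in range(level_ptr[lev], level_ptr[lev + 1]):
            rec = rec_order[t]
            ehat = e[rec]
            for a in range(k):
                ehat += rec_cov[rec, a] * theta[lev, a]
            for a in range(k):
                xa = rec_cov[rec, a]
                r[a] += xa * ehat
                for b in range(a + 1):
                    P[a, b] += xa * rec_cov[rec, b]
        for a in range(k):
            r[a] *= inv_s
            for b in range(a + 1):
                P[a, b] *= inv_s
        # prior contribution
        if use_ped:
            dii = 0.0
            for a in range(k):
                svec[a] = 0.0
            for ptr in range(ainv_indptr[lev], ainv_indptr[lev + 1]):
                j = ainv_indices[ptr]
                v = ainv_data[ptr]
                if j == lev:
                    dii = v
                else:
                    for a in range(k):
                        svec[a] += v * theta[j, a]
            for a in range(k):
                acc = 0.0
                for b in range(k):
                    acc += Qp[a, b] * svec[b]
                r[a] -= acc
                for b in range(a + 1):
                    P[a, b] += dii * Qp[a, b]
        else:
            for a in range(k):
                for b in range(a + 1):
                    P[a, b] += Qp[a, b]
        _cholesky(P, Lc, k)
        # mu = P^-1 r  via L L' mu = r
        for i in range(k):
            s = r[i]
            for m in range(i):
                s -= Lc[i, m] * u[m]
            u[i] = s / Lc[i, i]
        for i in range(k - 1, -1, -1):
            s = u[i]
            for m in range(i + 1, k):
                s -= Lc[m, i] * mu[m]
            mu[i] = s / Lc[i, i]
        # w = L'^-1 z  (draw with covariance P^-1)
        for i in range(k - 1, -1, -1):
            s = z[lev, i]
            for m in range(i + 1, k):
                s -= Lc[m, i] * w[m]
            w[i] = s / Lc[i, i]
        # residual update and write-back
        for t in range(level_ptr[lev], level_ptr[lev + 1]):
            rec = rec_order[t]
            de = 0.0
            for a in range(k):
                de += rec_cov[rec, a] * (mu[a] + w[a] - theta[lev, a])
            e[rec] -= de
        for a in range(k):
            theta[lev, a] = mu[a] + w[a]
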