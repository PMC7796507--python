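"""Compiled Metropolis-within-Gibbs kernel for the joint spatial model.

The update cycle per iteration:

1. blockwise random-walk Metropolis on (alpha_k, beta_k) for each disease;
2. single-site random-walk Metropolis sweeps over the shared field U, the
   disease-specific fields U_k, and the heterogeneity terms eps_k, with the
   structured fields re-centred to sum-to-zero after each sweep (the
   subtracted mean is transferred into alpha_k so the likelihood is
   unchanged exactly — this requires a connected graph);
3. random-walk Metropolis on log_delta (the shared-field risk gradient);
4. conjugate Gibbs draws for every precision.

Proposal step sizes adapt during burn-in toward 0.44 acceptance for
single-site moves and 0.234 for block moves, and are frozen afterwards.
All randomness flows from a single seed, so chains are bitwise
reproducible.  Everything here is numba-compiled; the public API lives in
:mod:`jointmap.mcmc_inference`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the step-scale / acceptance bookkeeping arrays
B_AB1, B_AB2, B_U, B_U1, B_U2, B_E1, B_E2, B_LD = range(8)
N_BLOCKS = 8


@njit(cache=True, fastmath=False)
def _log1pexp(x):
    # stable log(1 + exp(x))
    if x > 35.0:
        return x
    if x < -35.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


@njit(cache=True)
def _full_ll(y, xb, alpha, off, d):
    s = 0.0
    for i in range(y.shape[0]):
        eta = alpha + xb[i] + off[d[i]]
        s += y[i] * eta - _log1pexp(eta)
    return s


@njit(cache=True)
def _district_ll(y, xb, alpha, offj, dorder, dptr, j):
    s = 0.0
    for t in range(dptr[j], dptr[j + 1]):
        i = dorder[t]
        eta = alpha + xb[i] + offj
        s += y[i] * eta - _log1pexp(eta)
    return s


@njit(cache=True)
def _icar_local_delta(u, j, new_val, nbr_indptr, nbr_idx, tau):
    # change in -tau/2 * sum_{l ~ j} (u_j - u_l)^2 when u_j -> new_val
    old = u[j]
    acc = 0.0
    for t in range(nbr_indptr[j], nbr_indptr[j + 1]):
        l = nbr_idx[t]
        dn = new_val - u[l]
        do = old - u[l]
        acc += dn * dn - do * do
    return -0.5 * tau * acc


@njit(cache=True)
def _icar_penalty(u, nbr_indptr, nbr_idx):
    # sum over ordered pairs counts each edge twice
    acc = 0.0
    J = u.shape[0]
    for j in range(J):
        for t in range(nbr_indptr[j], nbr_indptr[j + 1]):
            l = nbr_idx[t]
            dlt = u[j] - u[l]
            acc += dlt * dlt
    return 0.5 * acc


@njit(cache=True)
def run_chain_core(
    y1, y2, X1, X2, d, dorder, dptr,
    nbr_indptr, nbr_idx, shared,
    sd_alpha, sd_beta, sd_log_delta, prec_shape, prec_rate,
    alpha_init, tau_init,
    iterations, burn_in, thin, adapt_interval, seed,
):
    np.random.seed(seed)
    n = y1.shape[0]
    p1 = X1.shape[1]
    p2 = X2.shape[1]
    J = dptr.shape[0] - 1
    nd = (iterations - burn_in) // thin

    # ---- state ----
    alpha1 = alpha_init[0]
    alpha2 = alpha_init[1]
    beta1 = np.zeros(p1)
    beta2 = np.zeros(p2)
    u = np.zeros(J)
    u1 = np.zeros(J)
    u2 = np.zeros(J)
    e1 = np.zeros(J)
    e2 = np.zeros(J)
    ld = 0.0
    g1 = 1.0
    g2 = 1.0
    tau_u = tau_init
    tau_u1 = tau_init
    tau_u2 = tau_init
    tau_e1 = tau_init
    tau_e2 = tau_init

    xb1 = X1 @ beta1
    xb2 = X2 @ beta2
    off1 = np.zeros(J)   # g1*u + u1 + e1
    off2 = np.zeros(J)

    # ---- adaptation bookkeeping ----
    log_step = np.zeros(N_BLOCKS)
    log_step[B_AB1] = math.log(0.1 / math.sqrt(p1 + 1.0))
    log_step[B_AB2] = math.log(0.1 / math.sqrt(p2 + 1.0))
    log_step[B_U] = math.log(0.5)
    log_step[B_U1] = math.log(0.5)
    log_step[B_U2] = math.log(0.5)
    log_step[B_E1] = math.log(0.5)
    log_step[B_E2] = math.log(0.5)
    log_step[B_LD] = math.log(0.1)
    target = np.empty(N_BLOCKS)
    for b in range(N_BLOCKS):
        target[b] = 0.44
    target[B_AB1] = 0.234
    target[B_AB2] = 0.234
    win_acc = np.zeros(N_BLOCKS)
    win_try = np.zeros(N_BLOCKS)
    post_acc = np.zeros(N_BLOCKS)
    post_try = np.zeros(N_BLOCKS)
    n_windows = 0

    # ---- storage ----
    alpha_out = np.empty((nd, 2))
    beta1_out = np.empty((nd, p1))
    beta2_out = np.empty((nd, p2))
    u_out = np.empty((nd, J))
    u1_out = np.empty((nd, J))
    u2_out = np.empty((nd, J))
    e1_out = np.empty((nd, J))
    e2_out = np.empty((nd, J))
    ld_out = np.empty(nd)
    tau_out = np.empty((nd, 5))
    keep = 0

    prior_a = prec_shape + 0.5 * (J - 1.0)   # ICAR fields (connected graph)
    prior_e = prec_shape + 0.5 * J           # iid heterogeneity

    for it in range(iterations):
        adapting = it < burn_in

        # ---- 1. (alpha_k, beta_k) blocks ----
        for k in range(2):
            b = B_AB1 if k == 0 else B_AB2
            s = math.exp(log_step[b])
            if k == 0:
                a_new = alpha1 + s * np.random.normal()
                bet_new = beta1 + s * np.random.standard_normal(p1)
                xb_new = X1 @ bet_new
                ll_old = _full_ll(y1, xb1, alpha1, off1, d)
                ll_new = _full_ll(y1, xb_new, a_new, off1, d)
                dprior = (
                    -0.5 * (a_new * a_new - alpha1 * alpha1) / (sd_alpha * sd_alpha)
                    - 0.5 * (np.sum(bet_new * bet_new) - np.sum(beta1 * beta1))
                    / (sd_beta * sd_beta)
                )
            else:
                a_new = alpha2 + s * np.random.normal()
                bet_new = beta2 + s * np.random.standard_normal(p2)
                xb_new = X2 @ bet_new
                ll_old = _full_ll(y2, xb2, alpha2, off2, d)
                ll_new = _full_ll(y2, xb_new, a_new, off2, d)
                dprior = (
                    -0.5 * (a_new * a_new - alpha2 * alpha2) / (sd_alpha * sd_alpha)
                    - 0.5 * (np.sum(bet_new * bet_new) - np.sum(beta2 * beta2))
                    / (sd_beta * sd_beta)
                )
            win_try[b] += 1.0
            if not adapting:
                post_try[b] += 1.0
            if math.log(np.random.random()) < ll_new - ll_old + dprior:
                if k == 0:
                    alpha1 = a_new
                    beta1 = bet_new
                    xb1 = xb_new
                else:
                    alpha2 = a_new
                    beta2 = bet_new
                    xb2 = xb_new
                win_acc[b] += 1.0
                if not adapting:
                    post_acc[b] += 1.0

        # ---- 2. shared field U (single-site) ----
        if shared:
            s = math.exp(log_step[B_U])
            for j in range(J):
                new_val = u[j] + s * np.random.normal()
                dprior = _icar_local_delta(u, j, new_val, nbr_indptr, nbr_idx, tau_u)
                duj = new_val - u[j]
                ll_old = _district_ll(y1, xb1, alpha1, off1[j], dorder, dptr, j) \
                    + _district_ll(y2, xb2, alpha2, off2[j], dorder, dptr, j)
                ll_new = _district_ll(y1, xb1, alpha1, off1[j] + g1 * duj, dorder, dptr, j) \
                    + _district_ll(y2, xb2, alpha2, off2[j] + g2 * duj, dorder, dptr, j)
                win_try[B_U] += 1.0
                if not adapting:
                    post_try[B_U] += 1.0
                if math.log(np.random.random()) < ll_new - ll_old + dprior:
                    u[j] = new_val
                    off1[j] += g1 * duj
                    off2[j] += g2 * duj
                    win_acc[B_U] += 1.0
                    if not adapting:
                        post_acc[B_U] += 1.0
            m = np.mean(u)
            for j in range(J):
                u[j] -= m
                off1[j] -= g1 * m
                off2[j] -= g2 * m
            alpha1 += g1 * m
            alpha2 += g2 * m

        # ---- 3./4. disease-specific fields ----
        for fk in range(2):
            b = B_U1 if fk == 0 else B_U2
            s = math.exp(log_step[b])
            if fk == 0:
                uf, tau_f, yk, xbk, ak, offk = u1, tau_u1, y1, xb1, alpha1, off1
            else:
                uf, tau_f, yk, xbk, ak, offk = u2, tau_u2, y2, xb2, alpha2, off2
            for j in range(J):
                new_val = uf[j] + s * np.random.normal()
                dprior = _icar_local_delta(uf, j, new_val, nbr_indptr, nbr_idx, tau_f)
                duj = new_val - uf[j]
                ll_old = _district_ll(yk, xbk, ak, offk[j], dorder, dptr, j)
                ll_new = _district_ll(yk, xbk, ak, offk[j] + duj, dorder, dptr, j)
                win_try[b] += 1.0
                if not adapting:
                    post_try[b] += 1.0
                if math.log(np.random.random()) < ll_new - ll_old + dprior:
                    uf[j] = new_val
                    offk[j] += duj
                    win_acc[b] += 1.0
                    if not adapting:
                        post_acc[b] += 1.0
            m = np.mean(uf)
            for j in range(J):
                uf[j] -= m
                offk[j] -= m
            if fk == 0:
                alpha1 += m
            else:
                alpha2 += m

        # ---- 5./6. heterogeneity ----
        for fk in range(2):
            b = B_E1 if fk == 0 else B_E2
            s = math.exp(log_step[b])
            if fk == 0:
                ef, tau_f, yk, xbk, ak, offk = e1, tau_e1, y1, xb1, alpha1, off1
            else:
                ef, tau_f, yk, xbk, ak, offk = e2, tau_e2, y2, xb2, alpha2, off2
            for j in range(J):
                new_val = ef[j] + s * np.random.normal()
                dprior = -0.5 * tau_f * (new_val * new_val - ef[j] * ef[j])
                duj = new_val - ef[j]
                ll_old = _district_ll(yk, xbk, ak, offk[j], dorder, dptr, j)
                ll_new = _district_ll(yk, xbk, ak, offk[j] + duj, dorder, dptr, j)
                win_try[b] += 1.0
                if not adapting:
                    post_try[b] += 1.0
                if math.log(np.random.random()) < ll_new - ll_old + dprior:
                    ef[j] = new_val
                    offk[j] += duj
                    win_acc[b] += 1.0
                    if not adapting:
                        post_acc[b] += 1.0

        # ---- 7. log_delta ----
        if shared:
            s = math.exp(log_step[B_LD])
            ld_new = ld + s * np.random.normal()
            g1n = math.exp(ld_new)
            g2n = math.exp(-ld_new)
            off1_new = off1 + (g1n - g1) * u
            off2_new = off2 + (g2n - g2) * u
            ll_old = _full_ll(y1, xb1, alpha1, off1, d) + _full_ll(y2, xb2, alpha2, off2, d)
            ll_new = _full_ll(y1, xb1, alpha1, off1_new, d) + _full_ll(y2, xb2, alpha2, off2_new, d)
            dprior = -0.5 * (ld_new * ld_new - ld * ld) / (sd_log_delta * sd_log_delta)
            win_try[B_LD] += 1.0
            if not adapting:
                post_try[B_LD] += 1.0
            if math.log(np.random.random()) < ll_new - ll_old + dprior:
                ld = ld_new
                g1 = g1n
                g2 = g2n
                off1 = off1_new
                off2 = off2_new
                win_acc[B_LD] += 1.0
                if not adapting:
                    post_acc[B_LD] += 1.0

        # ---- 8. conjugate Gibbs for precisions ----
        if shared:
            pen = _icar_penalty(u, nbr_indptr, nbr_idx)
            tau_u = np.random.gamma(prior_a, 1.0 / (prec_rate + 0.5 * pen))
        pen = _icar_penalty(u1, nbr_indptr, nbr_idx)
        tau_u1 = np.random.gamma(prior_a, 1.0 / (prec_rate + 0.5 * pen))
        pen = _icar_penalty(u2, nbr_indptr, nbr_idx)
        tau_u2 = np.random.gamma(prior_a, 1.0 / (prec_rate + 0.5 * pen))
        tau_e1 = np.random.gamma(prior_e, 1.0 / (prec_rate + 0.5 * np.sum(e1 * e1)))
        tau_e2 = np.random.gamma(prior_e, 1.0 / (prec_rate + 0.5 * np.sum(e2 * e2)))

        # ---- adaptation ----
        if adapting and (it + 1) % adapt_interval == 0:
            n_windows += 1
            delta = min(0.5, 2.0 / math.sqrt(n_windows))
            for b in range(N_BLOCKS):
                if win_try[b] > 0.0:
                    rate = win_acc[b] / win_try[b]
                    if rate > target[b]:
                        log_step[b] += delta
                    else:
                        log_step[b] -= delta
                win_acc[b] = 0.0
                win_try[b] = 0.0

        # ---- storage ----
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            alpha_out[keep, 0] = alpha1
            alpha_out[keep, 1] = alpha2
            beta1_out[keep] = beta1
            beta2_out[keep] = beta2
            u_out[keep] = u
            u1_out[keep] = u1
            u2_out[keep] = u2
            e1_out[keep] = e1
            e2_out[keep] = e2
            ld_out[keep] = ld
            tau_out[keep, 0] = tau_u
            tau_out[keep, 1] = tau_u1
            tau_out[keep, 2] = tau_u2
            tau_out[keep, 3] = tau_e1
            tau_out[keep, 4] = tau_e2
            keep += 1

    rates = np.zeros(N_BLOCKS)
    for b in range(N_BLOCKS):
        if post_try[b] > 0.0:
            rates[b] = post_acc[b] / post_try[b]
        else:
            rates[b] = np.nan
    return (
        alpha_out, beta1_out, beta2_out, u_out, u1_out, u2_out,
        e1_out, e2_out, ld_out, tau_out, rates,
    )
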