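"""Numba Gibbs kernel for K-population admixture inference.

Latent state: per-gene-copy cluster origin, cluster allele frequencies
(independent Dirichlet or correlated F-model around an ancestral
frequency), per-individual ancestry proportions q with a symmetric
Dirichlet(alpha) prior, and alpha itself (Metropolis, uniform prior on
(0, 10)).  The per-sweep data log-likelihood (with cluster origins
integrated out) is accumulated after burn-in; the run-level estimate is
mean - var/2 as in the reference implementation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MISSING = -1

ALPHA_MAX = 10.0
ALPHA_PROP_SD = 0.05
F_PROP_SD = 0.05
PA_PROP_SD = 0.05
LAMBDA = 1.0  # independent-model Dirichlet parameter


@njit(cache=True)
def _beta_logpdf(x, a, b):
    return (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
            + (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x))


@njit(cache=True)
def run_admixture_chain(calls, K, correlated, alpha_init, burn_in, sweeps, seed):
    """Returns (q_mean, lnP, alpha_mean)."""
    np.random.seed(seed)
    n, L = calls.shape

    p = np.random.uniform(0.1, 0.9, (K, L))  # cluster allele1 frequencies
    q = np.full((n, K), 1.0 / K)
    alpha = alpha_init
    F = np.full(K, 0.1)
    pA = np.full(L, 0.5)

    m = np.zeros((n, K))
    nk1 = np.zeros((L, K))
    nk2 = np.zeros((L, K))
    pT = np.empty((L, K))
    w = np.empty(K)
    q_sum = np.zeros((n, K))
    ll_sum = 0.0
    ll_sq = 0.0
    alpha_sum = 0.0
    kept = 0

    # K == 1: origins are deterministic, so the allele counts never change and
    # each sweep only redraws p and accumulates the log-likelihood.
    if K == 1:
        C1 = np.zeros(L)
        C2 = np.zeros(L)
        for i in range(n):
            for l in range(L):
                call = calls[i, l]
                if call != MISSING:
                    C2[l] += call
                    C1[l] += 2 - call
        for sweep in range(burn_in + sweeps):
            for l in range(L):
                if correlated:
                    fprime = (1.0 - F[0]) / F[0]
                    a = pA[l] * fprime + C1[l]
                    b = (1.0 - pA[l]) * fprime + C2[l]
                else:
                    a = LAMBDA + C1[l]
                    b = LAMBDA + C2[l]
                x = np.random.beta(a, b)
                if x < 1e-9:
                    x = 1e-9
                elif x > 1.0 - 1e-9:
                    x = 1.0 - 1e-9
                p[0, l] = x
            if correlated:
                for l in range(L):
                    prop = pA[l] + np.random.normal(0.0, PA_PROP_SD)
                    if 0.001 < prop < 0.999:
                        fprime = (1.0 - F[0]) / F[0]
                        logr = (_beta_logpdf(p[0, l], prop * fprime, (1.0 - prop) * fprime)
                                - _beta_logpdf(p[0, l], pA[l] * fprime,
                                               (1.0 - pA[l]) * fprime))
                        if logr >= 0.0 or np.random.random() < math.exp(logr):
                            pA[l] = prop
                prop = F[0] + np.random.normal(0.0, F_PROP_SD)
                if 0.001 < prop < 0.999:
                    fp_new = (1.0 - prop) / prop
                    fp_old = (1.0 - F[0]) / F[0]
                    logr = 0.0
                    for l in range(L):
                        logr += _beta_logpdf(p[0, l], pA[l] * fp_new,
                                             (1.0 - pA[l]) * fp_new)
                        logr -= _beta_logpdf(p[0, l], pA[l] * fp_old,
                                             (1.0 - pA[l]) * fp_old)
                    if logr >= 0.0 or np.random.random() < math.exp(logr):
                        F[0] = prop
            if sweep >= burn_in:
                kept += 1
                alpha_sum += alpha
                loglik = 0.0
                for l in range(L):
                    loglik += C1[l] * math.log(p[0, l]) + C2[l] * math.log(1.0 - p[0, l])
                ll_sum += loglik
                ll_sq += loglik * loglik
                for i in range(n):
                    q_sum[i, 0] += 1.0
        mean_ll = ll_sum / kept
        var_ll = ll_sq / kept - mean_ll * mean_ll
        if var_ll < 0.0:
            var_ll = 0.0
        return q_sum / kept, mean_ll - var_ll / 2.0, alpha_sum / kept

    total = burn_in + sweeps
    for sweep in range(total):
        record = sweep >= burn_in
        # --- cluster origins per gene copy, accumulating the log-likelihood
        for i in range(n):
            for k in range(K):
                m[i, k] = 0.0
        for l in range(L):
            for k in range(K):
                nk1[l, k] = 0.0
                nk2[l, k] = 0.0
                pT[l, k] = p[k, l]
        loglik = 0.0
        for i in range(n):
            qi = q[i]
            for l in range(L):
                call = calls[i, l]
                if call == MISSING:
                    continue
                if call == 1:  # het: one copy of each allele
                    for allele2 in range(2):
                        tot = 0.0
                        for k in range(K):
                            f = pT[l, k]
                            wk = qi[k] * ((1.0 - f) if allele2 == 1 else f)
                            w[k] = wk
                            tot += wk
                        target = np.random.random() * tot
                        acc = 0.0
                        kk = K - 1
                        for k in range(K):
                            acc += w[k]
                            if acc >= target:
                                kk = k
                                break
                        m[i, kk] += 1.0
                        if allele2 == 1:
                            nk2[l, kk] += 1.0
                        else:
                            nk1[l, kk] += 1.0
                        if record:
                            loglik += math.log(tot)
                else:  # hom: two copies of the same allele share the weights
                    a2 = call == 2
                    tot = 0.0
                    for k in range(K):
                        f = pT[l, k]
                        wk = qi[k] * ((1.0 - f) if a2 else f)
                        w[k] = wk
                        tot += wk
                    for _copy in range(2):
                        target = np.random.random() * tot
                        acc = 0.0
                        kk = K - 1
                        for k in range(K):
                            acc += w[k]
                            if acc >= target:
                                kk = k
                                break
                        m[i, kk] += 1.0
                        if a2:
                            nk2[l, kk] += 1.0
                        else:
                            nk1[l, kk] += 1.0
                    if record:
                        loglik += 2.0 * math.log(tot)

        # --- cluster allele frequencies ------------------------------------
        for k in range(K):
            if correlated:
                fprime = (1.0 - F[k]) / F[k]
            for l in range(L):
                if correlated:
                    a = pA[l] * fprime + nk1[l, k]
                    b = (1.0 - pA[l]) * fprime + nk2[l, k]
                else:
                    a = LAMBDA + nk1[l, k]
                    b = LAMBDA + nk2[l, k]
                x = np.random.beta(a, b)
                # guard against numerically degenerate draws
                if x < 1e-9:
                    x = 1e-9
                elif x > 1.0 - 1e-9:
                    x = 1.0 - 1e-9
                p[k, l] = x

        # --- correlated-model hyperparameters (Metropolis) -----------------
        if correlated:
            for l in range(L):
                prop = pA[l] + np.random.normal(0.0, PA_PROP_SD)
                if 0.001 < prop < 0.999:
                    logr = 0.0
                    for k in range(K):
                        fprime = (1.0 - F[k]) / F[k]
                        logr += _beta_logpdf(p[k, l], prop * fprime,
                                             (1.0 - prop) * fprime)
                        logr -= _beta_logpdf(p[k, l], pA[l] * fprime,
                                             (1.0 - pA[l]) * fprime)
                    if logr >= 0.0 or np.random.random() < math.exp(logr):
                        pA[l] = prop
            for k in range(K):
                prop = F[k] + np.random.normal(0.0, F_PROP_SD)
                if 0.001 < prop < 0.999:
                    fp_new = (1.0 - prop) / prop
                    fp_old = (1.0 - F[k]) / F[k]
                    logr = 0.0
                    for l in range(L):
                        logr += _beta_logpdf(p[k, l], pA[l] * fp_new,
                                             (1.0 - pA[l]) * fp_new)
                        logr -= _beta_logpdf(p[k, l], pA[l] * fp_old,
                                             (1.0 - pA[l]) * fp_old)
                    if logr >= 0.0 or np.random.random() < math.exp(logr):
                        F[k] = prop

        # --- ancestry proportions ------------------------------------------
        for i in range(n):
            tot = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + m[i, k], 1.0)
                if g < 1e-300:
                    g = 1e-300
                q[i, k] = g
                tot += g
            for k in range(K):
                q[i, k] /= tot

        # --- alpha (Metropolis, uniform prior on (0, ALPHA_MAX)) -----------
        if K > 1:
            prop = alpha + np.random.normal(0.0, ALPHA_PROP_SD)
            if 0.001 < prop < ALPHA_MAX:
                sumlog = 0.0
                for i in range(n):
                    for k in range(K):
                        sumlog += math.log(q[i, k])
                logr = (n * (math.lgamma(K * prop) - K * math.lgamma(prop)
                             - math.lgamma(K * alpha) + K * math.lgamma(alpha))
                        + (prop - alpha) * sumlog)
                if logr >= 0.0 or np.random.random() < math.exp(logr):
                    alpha = prop

        if record:
            kept += 1
            alpha_sum += alpha
            ll_sum += loglik
            ll_sq += loglik * loglik
            for i in range(n):
                for k in range(K):
                    q_sum[i, k] += q[i, k]

    mean_ll = ll_sum / kept
    var_ll = ll_sq / kept - mean_ll * mean_ll
    if var_ll < 0.0:
        var_ll = 0.0
    lnP = mean_ll - var_ll / 2.0
    return q_sum / kept, lnP, alpha_sum / kept
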