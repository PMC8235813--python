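"""Numba Gibbs kernel for the genotype-frequency-class classifier.

Latent state: per-individual category z, per-gene-copy species origin
(resampled each sweep), per-species per-locus allele frequencies theta and
category mixing proportions pi.  Sweep order: origins -> theta ->
categories -> pi.  Categories are drawn with origins integrated out (a
block update), which keeps the chain valid and mixes faster.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MISSING = -1


@njit(cache=True)
def _sample_categorical(w, u):
    """Draw an index from unnormalised weights `w` using uniform `u`."""
    total = 0.0
    for i in range(w.size):
        total += w[i]
    acc = 0.0
    target = u * total
    for i in range(w.size):
        acc += w[i]
        if acc >= target:
            return i
    return w.size - 1


@njit(cache=True)
def run_classifier(calls, g, clamped, pi_prior, theta_prior, burn_in, sweeps, seed,
                   theta_init):
    """Run the Gibbs sampler; returns (visit_q, rb_q, theta_mean).

    calls      (n, L) int8; -1 missing, else allele2 dosage
    g          (C, 3) float64 origin-profile triples
    clamped    (n,) int64; -1 free, else fixed category index
    theta_init (2, L) float64 initial allele1 frequencies (wolf row 0)
    """
    np.random.seed(seed)
    n, L = calls.shape
    C = g.shape[0]

    theta = theta_init.copy()
    pi = np.full(C, 1.0 / C)
    z = np.empty(n, dtype=np.int64)
    for i in range(n):
        z[i] = clamped[i] if clamped[i] >= 0 else np.random.randint(0, C)

    visit = np.zeros((n, C))
    rb = np.zeros((n, C))
    theta_sum = np.zeros((2, L))
    kept = 0

    w1 = np.zeros(L)  # wolf allele1 copy counts
    w2 = np.zeros(L)
    d1 = np.zeros(L)
    d2 = np.zeros(L)
    ll = np.zeros((L, 3, C))  # call-major layout: contiguous over categories
    weights = np.zeros(4)
    logits = np.zeros(C)
    probs = np.zeros(C)

    total = burn_in + sweeps
    for sweep in range(total):
        # --- gene-copy origins (given z, theta) -> allele-origin counts ----
        for l in range(L):
            w1[l] = 0.0
            w2[l] = 0.0
            d1[l] = 0.0
            d2[l] = 0.0
        for i in range(n):
            c = z[i]
            g0 = g[c, 0]
            g1 = g[c, 1]
            g2 = g[c, 2]
            for l in range(L):
                call = calls[i, l]
                if call == MISSING:
                    continue
                p = theta[0, l]
                q = theta[1, l]
                if call == 0:  # two allele1 copies
                    weights[0] = g0 * p * p
                    weights[1] = g1 * p * q
                    weights[2] = g2 * q * q
                    k = _sample_categorical(weights[:3], np.random.random())
                    if k == 0:
                        w1[l] += 2.0
                    elif k == 1:
                        w1[l] += 1.0
                        d1[l] += 1.0
                    else:
                        d1[l] += 2.0
                elif call == 2:  # two allele2 copies
                    weights[0] = g0 * (1.0 - p) * (1.0 - p)
                    weights[1] = g1 * (1.0 - p) * (1.0 - q)
                    weights[2] = g2 * (1.0 - q) * (1.0 - q)
                    k = _sample_categorical(weights[:3], np.random.random())
                    if k == 0:
                        w2[l] += 2.0
                    elif k == 1:
                        w2[l] += 1.0
                        d2[l] += 1.0
                    else:
                        d2[l] += 2.0
                else:  # het: ordered copies carry allele1, allele2
                    weights[0] = g0 * p * (1.0 - p)
                    weights[1] = 0.5 * g1 * p * (1.0 - q)
                    weights[2] = 0.5 * g1 * q * (1.0 - p)
                    weights[3] = g2 * q * (1.0 - q)
                    k = _sample_categorical(weights, np.random.random())
                    if k == 0:
                        w1[l] += 1.0
                        w2[l] += 1.0
                    elif k == 1:
                        w1[l] += 1.0
                        d2[l] += 1.0
                    elif k == 2:
                        d1[l] += 1.0
                        w2[l] += 1.0
                    else:
                        d1[l] += 1.0
                        d2[l] += 1.0

        # --- theta (conjugate Beta given origin-labelled allele counts) ----
        for l in range(L):
            theta[0, l] = np.random.beta(theta_prior + w1[l], theta_prior + w2[l])
            theta[1, l] = np.random.beta(theta_prior + d1[l], theta_prior + d2[l])

        # --- per-call log-likelihood table ---------------------------------
        for l in range(L):
            p = theta[0, l]
            q = theta[1, l]
            for c in range(C):
                g0 = g[c, 0]
                g1 = g[c, 1]
                g2 = g[c, 2]
                ll[l, 0, c] = np.log(g0 * p * p + g1 * p * q + g2 * q * q)
                ll[l, 1, c] = np.log(
                    g0 * 2.0 * p * (1.0 - p)
                    + g1 * (p * (1.0 - q) + q * (1.0 - p))
                    + g2 * 2.0 * q * (1.0 - q)
                )
                ll[l, 2, c] = np.log(
                    g0 * (1.0 - p) * (1.0 - p)
                    + g1 * (1.0 - p) * (1.0 - q)
                    + g2 * (1.0 - q) * (1.0 - q)
                )

        # --- categories (origins integrated out) ---------------------------
        record = sweep >= burn_in
        for i in range(n):
            if clamped[i] >= 0:
                z[i] = clamped[i]
                if record:
                    visit[i, clamped[i]] += 1.0
                    rb[i, clamped[i]] += 1.0
                continue
            for c in range(C):
                logits[c] = np.log(pi[c])
            for l in range(L):
                call = calls[i, l]
                if call != MISSING:
                    for c in range(C):
                        logits[c] += ll[l, call, c]
            mx = logits[0]
            for c in range(1, C):
                if logits[c] > mx:
                    mx = logits[c]
            tot = 0.0
            for c in range(C):
                probs[c] = np.exp(logits[c] - mx)
                tot += probs[c]
            z[i] = _sample_categorical(probs, np.random.random())
            if record:
                visit[i, z[i]] += 1.0
                for c in range(C):
                    rb[i, c] += probs[c] / tot

        # --- pi (Dirichlet over free individuals) --------------------------
        tot = 0.0
        for c in range(C):
            cnt = pi_prior
            for i in range(n):
                if clamped[i] < 0 and z[i] == c:
                    cnt += 1.0
            pi[c] = np.random.gamma(cnt, 1.0)
            tot += pi[c]
        for c in range(C):
            pi[c] /= tot

        if record:
            kept += 1
            for l in range(L):
                theta_sum[0, l] += theta[0, l]
                theta_sum[1, l] += theta[1, l]

    for i in range(n):
        for c in range(C):
            visit[i, c] /= kept
            rb[i, c] /= kept
    return visit, rb, theta_sum / kept
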