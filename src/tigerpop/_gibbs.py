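"""JIT-compiled Gibbs sweep for the admixture clustering model.

Independent-allele-frequency admixture model: each individual i has
cluster membership proportions Q_i ~ Dirichlet(alpha); each allele copy
independently originates from cluster k with probability Q_ik and is
then drawn from that cluster's allele frequencies, themselves given a
symmetric Dirichlet(lambda) prior.  One sweep resamples copy origins z,
cluster frequencies, Q, and (for K > 1) the admixture parameter alpha by
a Metropolis step.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_chain(geno, K, A, burn_in, reps, lam, alpha0, alpha_sd, seed):
    """Run one chain; returns (Q mean, freq mean, per-sweep log-likelihoods,
    final alpha) over the ``reps`` post-burn-in sweeps.

    ``geno`` is (N, L, 2) int64 with allele codes 0..A-1 and -1 missing.
    """
    np.random.seed(seed)
    N, L, _ = geno.shape
    sweeps = burn_in + reps
    freq = np.full((K, L, A), 1.0 / A)
    Q = np.full((N, K), 1.0 / K)
    alpha = alpha0
    logls = np.empty(reps)
    q_sum = np.zeros((N, K))
    freq_sum = np.zeros((K, L, A))
    pk = np.empty(K)
    tiny = 1e-300
    for s in range(sweeps):
        counts = np.zeros((K, L, A))
        qcounts = np.zeros((N, K))
        logl = 0.0
        for i in range(N):
            for l in range(L):
                for c in range(2):
                    a = geno[i, l, c]
                    if a < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        v = Q[i, k] * freq[k, l, a]
                        pk[k] = v
                        tot += v
                    logl += math.log(tot + tiny)
                    u = np.random.random() * tot
                    kk = K - 1
                    acc = 0.0
                    for k in range(K - 1):
                        acc += pk[k]
                        if u < acc:
                            kk = k
                            break
                    counts[kk, l, a] += 1.0
                    qcounts[i, kk] += 1.0
        for k in range(K):
            for l in range(L):
                tot = 0.0
                for a in range(A):
                    g = np.random.gamma(lam + counts[k, l, a], 1.0) + tiny
                    freq[k, l, a] = g
                    tot += g
                for a in range(A):
                    freq[k, l, a] /= tot
        sum_log_q = 0.0
        for i in range(N):
            tot = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + qcounts[i, k], 1.0) + tiny
                Q[i, k] = g
                tot += g
            for k in range(K):
                Q[i, k] /= tot
                sum_log_q += math.log(Q[i, k] + tiny)
        if K > 1:
            prop = alpha + np.random.normal() * alpha_sd
            if 0.0 < prop < 10.0:
                logr = N * (
                    (math.lgamma(K * prop) - K * math.lgamma(prop))
                    - (math.lgamma(K * alpha) - K * math.lgamma(alpha))
                )
                logr += (prop - alpha) * sum_log_q
                if math.log(np.random.random() + tiny) < logr:
                    alpha = prop
        if s >= burn_in:
            logls[s - burn_in] = logl
            q_sum += Q
            freq_sum += freq
    return q_sum / reps, freq_sum / reps, logls, alpha
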