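"""Numba inner loops for the collapsed Gibbs sampler and the left-to-right
held-out likelihood estimator.

Token data is flattened: per-token participant index ``d_idx``, question
index ``q_idx`` and global answer index ``v_idx`` (the question's offset into
a concatenated vocabulary plus the within-question answer index).  Count
tables are the collapsed model's sufficient statistics.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep_kernel(z, d_idx, q_idx, v_idx, Vq, c_dk, c_kv, c_kq,
                       alpha, beta, seed):  # pragma: no cover - jitted
    """One systematic-scan sweep, resampling every token in stored order.

    P(z_i = k | rest) ~ (c_dk + alpha) * (c_kv + beta) / (c_kq + V_q beta),
    with the current token removed from all counts; V_q is the vocabulary
    size of the token's own question.
    """
    np.random.seed(seed)
    N = z.shape[0]
    K = c_dk.shape[1]
    p = np.empty(K)
    for i in range(N):
        d = d_idx[i]
        q = q_idx[i]
        v = v_idx[i]
        k_old = z[i]
        c_dk[d, k_old] -= 1
        c_kv[k_old, v] -= 1
        c_kq[k_old, q] -= 1
        total = 0.0
        for k in range(K):
            p[k] = (
                (c_dk[d, k] + alpha)
                * (c_kv[k, v] + beta)
                / (c_kq[k, q] + Vq[q] * beta)
            )
            total += p[k]
        u = np.random.random() * total
        acc = 0.0
        k_new = K - 1
        for k in range(K):
            acc += p[k]
            if u < acc:
                k_new = k
                break
        z[i] = k_new
        c_dk[d, k_new] += 1
        c_kv[k_new, v] += 1
        c_kq[k_new, q] += 1


@njit(cache=True)
def left_to_right_kernel(w_idx, q_of_token, phi_flat, alpha, R, seed
                         ):  # pragma: no cover - jitted
    """Left-to-right particle weights for log p(doc | Phi, alpha).

    ``w_idx[n]`` is token n's global answer index into ``phi_flat`` (K rows,
    concatenated vocabulary columns); emission for each token uses its own
    question's phi block, while the theta-counts are shared across questions
    within the document.  Each particle sweeps the document once left to
    right, rejuvenating the earlier labels by one Gibbs pass per position and
    accumulating log incremental weights log p(w_n | z_{<n}); returns the
    (R,) per-particle log weights, whose exponential mean is an unbiased
    estimate of the document likelihood.
    """
    np.random.seed(seed)
    N = w_idx.shape[0]
    K = phi_flat.shape[0]
    Kalpha = K * alpha
    z = np.zeros((R, N), dtype=np.int64)
    counts = np.zeros((R, K), dtype=np.int64)
    log_weight = np.zeros(R)
    p = np.empty(K)
    for n in range(N):
        wn = w_idx[n]
        for r in range(R):
            # one resampling pass over positions < n given Phi
            for m in range(n):
                wm = w_idx[m]
                k_old = z[r, m]
                counts[r, k_old] -= 1
                tot = 0.0
                for k in range(K):
                    p[k] = (counts[r, k] + alpha) * phi_flat[k, wm]
                    tot += p[k]
                u = np.random.random() * tot
                acc = 0.0
                k_new = K - 1
                for k in range(K):
                    acc += p[k]
                    if u < acc:
                        k_new = k
                        break
                z[r, m] = k_new
                counts[r, k_new] += 1
            # predictive probability of token n, then sample its label
            tot = 0.0
            pred = 0.0
            for k in range(K):
                p[k] = (counts[r, k] + alpha) * phi_flat[k, wn]
                tot += p[k]
                pred += (counts[r, k] + alpha) / (n + Kalpha) * phi_flat[k, wn]
            log_weight[r] += np.log(pred)
            u = np.random.random() * tot
            acc = 0.0
            k_new = K - 1
            for k in range(K):
                acc += p[k]
                if u < acc:
                    k_new = k
                    break
            z[r, n] = k_new
            counts[r, k_new] += 1
    return log_weight
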