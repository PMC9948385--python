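"""Numba inner loop for the collapsed Gibbs sampler.

Kept in its own module so the jitted kernel compiles once per process and the
public ``lda`` module stays readable.  The kernel mutates the count matrices in
place; correctness of the bookkeeping is asserted by recount oracles in the
test suite rather than inside the hot loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep_kernel(words, docs, z, Cwk, Cdk, topic_totals, alpha, beta, u):
    """One full sweep: resample every token in order (doc-major).

    ``u`` holds one uniform variate per token, drawn by the caller so all
    randomness lives in a numpy ``Generator``.  The per-token conditional is
    proportional to ``(Cwk[w,j]+beta)/(topic_totals[j]+W*beta) * (Cdk[d,j]+alpha)``;
    the document denominator is constant over topics and cancels.
    """
    T = words.shape[0]
    W = Cwk.shape[0]
    K = Cwk.shape[1]
    cum = np.empty(K, dtype=np.float64)
    for i in range(T):
        w = words[i]
        d = docs[i]
        k = z[i]
        Cwk[w, k] -= 1
        Cdk[d, k] -= 1
        topic_totals[k] -= 1
        s = 0.0
        for j in range(K):
            s += (
                (Cwk[w, j] + beta)
                / (topic_totals[j] + W * beta)
                * (Cdk[d, j] + alpha)
            )
            cum[j] = s
        r = u[i] * s
        k_new = K - 1
        for j in range(K):
            if cum[j] > r:
                k_new = j
                break
        z[i] = k_new
        Cwk[w, k_new] += 1
        Cdk[d, k_new] += 1
        topic_totals[k_new] += 1
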