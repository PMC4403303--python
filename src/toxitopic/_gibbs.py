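"""Numba kernels for the collapsed Gibbs sweeps.

Kept free of any Python-object state so the hot loops compile to machine
code; randomness enters only through pre-drawn uniform variates, which
keeps every sweep reproducible from a single seeded generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep(z, tok_word, tok_author, n_ak, n_kw, n_k, alpha, beta, u):
    """One collapsed sweep: resample every token's topic in order.

    Conditional for token i with word w and author a:
        p(z_i = k | rest) ∝ (n_ak[a,k] + alpha[k]) * (n_kw[k,w] + beta)
                            / (n_k[k] + V*beta)
    with token i removed from all counts.  ``u`` holds one uniform
    variate per token.
    """
    n_tokens = z.shape[0]
    n_topics = n_k.shape[0]
    v_beta = n_kw.shape[1] * beta
    cum = np.empty(n_topics, dtype=np.float64)
    for i in range(n_tokens):
        w = tok_word[i]
        a = tok_author[i]
        k = z[i]
        n_ak[a, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        total = 0.0
        for t in range(n_topics):
            total += (n_ak[a, t] + alpha[t]) * (n_kw[t, w] + beta) / (n_k[t] + v_beta)
            cum[t] = total
        r = u[i] * total
        k_new = 0
        while k_new < n_topics - 1 and cum[k_new] <= r:
            k_new += 1
        z[i] = k_new
        n_ak[a, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1


@njit(cache=True)
def fold_in_sweep(z, tok_word, tok_doc, n_dk, phi, alpha, u):
    """One fold-in sweep for held-out documents with topics frozen.

    Conditional: p(z_i = k | rest) ∝ (n_dk[d,k] + alpha[k]) * phi[k, w].
    """
    n_tokens = z.shape[0]
    n_topics = phi.shape[0]
    cum = np.empty(n_topics, dtype=np.float64)
    for i in range(n_tokens):
        w = tok_word[i]
        d = tok_doc[i]
        k = z[i]
        n_dk[d, k] -= 1
        total = 0.0
        for t in range(n_topics):
            total += (n_dk[d, t] + alpha[t]) * phi[t, w]
            cum[t] = total
        r = u[i] * total
        k_new = 0
        while k_new < n_topics - 1 and cum[k_new] <= r:
            k_new += 1
        z[i] = k_new
        n_dk[d, k_new] += 1
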