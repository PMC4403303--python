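"""Exact small-corpus references for validating the sampler.

These routines recompute posterior quantities by brute-force enumeration
of every topic-assignment vector, entirely independently of the
incremental Gibbs bookkeeping, so they serve as ground truth on corpora
small enough to enumerate (K**N assignment vectors).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln

from toxitopic.corpus import CountCorpus


def collapsed_log_joint(
    z: np.ndarray,
    tok_word: np.ndarray,
    tok_author: np.ndarray,
    n_authors: int,
    n_vocab: int,
    alpha: np.ndarray,
    beta: float,
) -> float:
    """log p(w, z | alpha, beta) for one full assignment vector, computed
    from scratch by tallying z (no incremental counts)."""
    K = alpha.shape[0]
    n_ak = np.zeros((n_authors, K))
    n_kw = np.zeros((K, n_vocab))
    n_k = np.zeros(K)
    np.add.at(n_ak, (tok_author, z), 1)
    np.add.at(n_kw, (z, tok_word), 1)
    np.add.at(n_k, z, 1)
    n_a = n_ak.sum(axis=1)
    author_side = (
        np.sum(gammaln(n_ak + alpha))
        - n_authors * np.sum(gammaln(alpha))
        + n_authors * gammaln(alpha.sum())
        - np.sum(gammaln(n_a + alpha.sum()))
    )
    word_side = (
        np.sum(gammaln(n_kw + beta))
        - K * n_vocab * gammaln(beta)
        + K * gammaln(n_vocab * beta)
        - np.sum(gammaln(n_k + n_vocab * beta))
    )
    return float(author_side + word_side)


def enumerate_posterior_marginals(
    corpus: CountCorpus, K: int, alpha: np.ndarray, beta: float
) -> np.ndarray:
    """Exact per-token posterior P(z_i = k | w) by enumerating all K**N
    assignment vectors.  Returns an (N, K) matrix in the token order of
    ``CountCorpus.token_arrays``."""
    _, tok_word, tok_author = corpus.token_arrays()
    N = tok_word.shape[0]
    if K**N > 2_000_000:
        raise ValueError("corpus too large to enumerate")
    alpha = np.asarray(alpha, dtype=float)
    log_ps = []
    assignments = []
    for zs in itertools.product(range(K), repeat=N):
        z = np.array(zs, dtype=np.int64)
        assignments.append(z)
        log_ps.append(
            collapsed_log_joint(
                z, tok_word, tok_author, corpus.n_authors, corpus.n_vocab, alpha, beta
            )
        )
    log_ps = np.array(log_ps)
    w = np.exp(log_ps - log_ps.max())
    w /= w.sum()
    marg = np.zeros((N, K))
    for weight, z in zip(w, assignments):
        marg[np.arange(N), z] += weight
    return marg
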