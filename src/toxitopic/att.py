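"""Collapsed Gibbs inference for the asymmetric author-topic model.

Each treatment document is written by exactly one author (the treatment
itself, its drug, or its dose-time pair), so the author-sampling step of
the general author-topic model degenerates to grouped LDA: topics are
drawn per author with an asymmetric Dirichlet prior ``alpha`` (learned by
Minka's fixed point) and genes per topic with a symmetric prior ``beta``.

The latent "topics" are latent biological processes: probability
distributions over genes representing co-regulated modules whose mixing
weights P(Z|feature) characterize each treatment, drug, or dose-time
combination.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi

from toxitopic import _gibbs
from toxitopic.corpus import CountCorpus

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8


@dataclass
class HyperParams:
    """Dirichlet concentrations: asymmetric ``alpha`` over the K latent
    processes (prior on P(Z|author)) and symmetric ``beta`` on genes."""

    alpha: np.ndarray
    beta: float
    K: int

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha.shape != (self.K,) or np.any(self.alpha <= 0):
            raise ValueError("alpha must be a length-K vector of positive reals")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class ATTState:
    """Sampler state: per-token assignments plus the implied count tables."""

    z: np.ndarray  # token -> topic
    tok_doc: np.ndarray
    tok_word: np.ndarray
    tok_author: np.ndarray
    n_ak: np.ndarray  # author x topic
    n_kw: np.ndarray  # topic x gene
    n_k: np.ndarray  # topic totals
    hyper: HyperParams
    rng: np.random.Generator
    rng_seed: int

    @property
    def n_authors(self) -> int:
        return self.n_ak.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.n_kw.shape[1]

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Independent tally of z — the consistency oracle for the
        incremental updates."""
        K = self.hyper.K
        n_ak = np.zeros_like(self.n_ak)
        n_kw = np.zeros_like(self.n_kw)
        n_k = np.zeros_like(self.n_k)
        np.add.at(n_ak, (self.tok_author, self.z), 1)
        np.add.at(n_kw, (self.z, self.tok_word), 1)
        np.add.at(n_k, self.z, 1)
        return n_ak, n_kw, n_k

    def check_consistent(self) -> None:
        n_ak, n_kw, n_k = self.recount()
        if not (
            np.array_equal(n_ak, self.n_ak)
            and np.array_equal(n_kw, self.n_kw)
            and np.array_equal(n_k, self.n_k)
        ):
            raise ValueError("sampler state inconsistent: count tables do not match z")


def initialize_state(
    corpus: CountCorpus,
    K: int,
    alpha0: float = 50.0,
    beta0: float = 0.01,
    seed: int = 0,
) -> ATTState:
    """Seeded uniform-random topic assignment with consistent count tables.

    ``alpha0`` is the total prior concentration; the starting prior is
    symmetric at ``alpha0 / K`` per component and becomes asymmetric once
    ``optimize_alpha`` runs.
    """
    if corpus.n_docs == 0 or corpus.n_tokens == 0:
        raise ValueError("cannot initialize the sampler on an empty corpus")
    if K < 1:
        raise ValueError("K must be >= 1")
    hyper = HyperParams(alpha=np.full(K, alpha0 / K), beta=float(beta0), K=K)
    rng = np.random.default_rng(seed)
    tok_doc, tok_word, tok_author = corpus.token_arrays()
    z = rng.integers(0, K, size=tok_doc.shape[0]).astype(np.int64)
    state = ATTState(
        z=z,
        tok_doc=tok_doc,
        tok_word=tok_word,
        tok_author=tok_author,
        n_ak=np.zeros((corpus.n_authors, K), dtype=np.int64),
        n_kw=np.zeros((K, corpus.n_vocab), dtype=np.int64),
        n_k=np.zeros(K, dtype=np.int64),
        hyper=hyper,
        rng=rng,
        rng_seed=int(seed),
    )
    state.n_ak, state.n_kw, state.n_k = state.recount()
    return state


def gibbs_sweep(state: ATTState, check: bool = False) -> ATTState:
    """Resample every token once (document order, token order within
    document), updating count tables in place."""
    if check:
        state.check_consistent()
    u = state.rng.random(state.z.shape[0])
    _gibbs.sweep(
        state.z,
        state.tok_word,
        state.tok_author,
        state.n_ak,
        state.n_kw,
        state.n_k,
        state.hyper.alpha,
        state.hyper.beta,
        u,
    )
    return state


def joint_log_likelihood(state: ATTState) -> float:
    """Collapsed joint log p(w, z | alpha, beta) up to token-order
    constants; the per-sweep convergence trace."""
    alpha = state.hyper.alpha
    beta = state.hyper.beta
    K = state.hyper.K
    V = state.n_vocab
    alpha_sum = alpha.sum()
    n_a = state.n_ak.sum(axis=1)

    author_side = (
        np.sum(gammaln(state.n_ak + alpha))
        - state.n_authors * np.sum(gammaln(alpha))
        + state.n_authors * gammaln(alpha_sum)
        - np.sum(gammaln(n_a + alpha_sum))
    )
    word_side = (
        np.sum(gammaln(state.n_kw + beta))
        - K * V * gammaln(beta)
        + K * gammaln(V * beta)
        - np.sum(gammaln(state.n_k + V * beta))
    )
    return float(author_side + word_side)


def minka_fixed_point(
    counts: np.ndarray,
    alpha_init: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    floor: float = ALPHA_FLOOR,
) -> np.ndarray:
    """Maximum-likelihood Dirichlet concentration for Dirichlet-multinomial
    count rows via Minka's fixed point:

        alpha_k <- alpha_k * [sum_a psi(n_ak + alpha_k) - A psi(alpha_k)]
                           / [sum_a psi(N_a + sum alpha) - A psi(sum alpha)]

    iterated until the maximum relative change drops below ``tol``.
    Components are clamped at ``floor`` rather than zeroed.
    """
    counts = np.asarray(counts, dtype=float)
    n_a = counts.sum(axis=1)
    A = counts.shape[0]
    alpha = np.asarray(alpha_init, dtype=float).copy()
    for _ in range(max_iter):
        alpha_sum = alpha.sum()
        num = psi(counts + alpha).sum(axis=0) - A * psi(alpha)
        den = psi(n_a + alpha_sum).sum() - A * psi(alpha_sum)
        new = np.maximum(alpha * num / den, floor)
        rel = np.max(np.abs(new - alpha) / np.maximum(alpha, floor))
        alpha = new
        if rel < tol:
            break
    return alpha


def optimize_alpha(
    state: ATTState,
    tol: float = 1e-6,
    max_iter: int = 1000,
    floor: float = ALPHA_FLOOR,
) -> ATTState:
    """Re-estimate the asymmetric Dirichlet prior from the current
    author-topic counts by Minka's fixed point (authors with no tokens are
    excluded; an all-zero table leaves alpha unchanged with a warning)."""
    counts = state.n_ak[state.n_ak.sum(axis=1) > 0]
    if counts.size == 0 or counts.sum() == 0:
        warnings.warn("all-zero author-topic table; alpha left unchanged")
        return state
    state.hyper.alpha = minka_fixed_point(
        counts, state.hyper.alpha, tol=tol, max_iter=max_iter, floor=floor
    )
    return state


def estimate_theta(state: ATTState) -> np.ndarray:
    """Posterior-mean P(Z | author): (n_ak + alpha_k) / (N_a + sum alpha)."""
    alpha = state.hyper.alpha
    n_a = state.n_ak.sum(axis=1, keepdims=True)
    if np.any(n_a == 0):
        warnings.warn("author(s) with zero tokens: theta row equals the prior mean")
    return (state.n_ak + alpha) / (n_a + alpha.sum())


def estimate_phi(state: ATTState, smoothed: bool = True) -> np.ndarray:
    """Posterior-mean P(Ge | Z).

    Smoothed: ``(n_kw + beta) / (n_k + V beta)`` — strictly positive, used
    for perplexity and sKL.  Raw: ``n_kw / n_k`` with exact zeros for
    genes never assigned to the process — the sparse support used for
    gene lists; a process with no tokens gets an all-zero (empty) row.
    """
    if smoothed:
        beta = state.hyper.beta
        return (state.n_kw + beta) / (state.n_k[:, None] + state.n_vocab * beta)
    n_k = state.n_k.astype(float)
    empty = n_k == 0
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} empty topic(s) in raw phi")
    denom = np.where(empty, 1.0, n_k)
    return state.n_kw / denom[:, None]


@dataclass
class ATTModel:
    """Point estimates and training metadata of a fitted model."""

    theta: np.ndarray  # author x topic
    phi_smoothed: np.ndarray  # topic x gene
    phi_raw: np.ndarray  # topic x gene, exact zeros preserved
    hyper: HyperParams
    author_ids: list[str]
    vocabulary: list[str]
    feature_level: str
    loglik: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int = 0
    iterations: int = 0
    empty_topics: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    final_loglik: float = float("nan")  # collapsed joint log p(w, z) at the last sweep

    def validate(self) -> None:
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.phi_smoothed.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi_smoothed rows must sum to 1")
        raw_sums = self.phi_raw.sum(axis=1)
        ok = np.isclose(raw_sums, 1.0, atol=1e-9) | self.empty_topics
        if not np.all(ok):
            raise ValueError("phi_raw rows must sum to 1 over their support or be empty")

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        topics = [f"topic_{k}" for k in range(self.hyper.K)]
        pd.DataFrame(self.theta, index=self.author_ids, columns=topics).to_csv(
            out / "theta.tsv", sep="\t", index_label="author"
        )
        pd.DataFrame(self.phi_smoothed, index=topics, columns=self.vocabulary).to_csv(
            out / "phi_smoothed.tsv", sep="\t", index_label="topic"
        )
        with open(out / "phi_raw.tsv", "w") as fh:  # sparse triples
            fh.write("topic\tgene\tprobability\n")
            for k, w in zip(*np.nonzero(self.phi_raw)):
                fh.write(f"{k}\t{self.vocabulary[w]}\t{self.phi_raw[k, w]:.17g}\n")
        meta = {
            "alpha": self.hyper.alpha.tolist(),
            "beta": self.hyper.beta,
            "K": self.hyper.K,
            "seed": self.seed,
            "iterations": self.iterations,
            "feature_level": self.feature_level,
            "empty_topics": np.nonzero(self.empty_topics)[0].tolist(),
        }
        (out / "hyper.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame({"sweep": np.arange(len(self.loglik)), "loglik": self.loglik}).to_csv(
            out / "loglik.tsv", sep="\t", index=False
        )
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "ATTModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "hyper.json").read_text())
        theta_df = pd.read_csv(in_dir / "theta.tsv", sep="\t", index_col="author")
        phi_s_df = pd.read_csv(in_dir / "phi_smoothed.tsv", sep="\t", index_col="topic")
        phi_s_df.columns = phi_s_df.columns.astype(str)
        vocabulary = list(phi_s_df.columns)
        vocab_index = {g: j for j, g in enumerate(vocabulary)}
        K = int(meta["K"])
        phi_raw = np.zeros((K, len(vocabulary)))
        raw = pd.read_csv(in_dir / "phi_raw.tsv", sep="\t", dtype={"gene": str})
        for _, row in raw.iterrows():
            phi_raw[int(row["topic"]), vocab_index[row["gene"]]] = row["probability"]
        empty = np.zeros(K, dtype=bool)
        empty[meta.get("empty_topics", [])] = True
        loglik = pd.read_csv(in_dir / "loglik.tsv", sep="\t")["loglik"].to_numpy()
        return cls(
            theta=theta_df.to_numpy(),
            phi_smoothed=phi_s_df.to_numpy(),
            phi_raw=phi_raw,
            hyper=HyperParams(np.array(meta["alpha"]), float(meta["beta"]), K),
            author_ids=[str(a) for a in theta_df.index],
            vocabulary=vocabulary,
            feature_level=meta.get("feature_level", "treatment"),
            loglik=loglik,
            seed=int(meta.get("seed", 0)),
            iterations=int(meta.get("iterations", 0)),
            empty_topics=empty,
        )


def train(
    corpus: CountCorpus,
    K: int,
    iterations: int = 3000,
    burn_in: int = 200,
    optimize_interval: int = 10,
    alpha0: float = 50.0,
    beta0: float = 0.01,
    seed: int = 0,
    optimize_hyper: bool = True,
    loglik_every: int = 1,
    average_samples: int = 0,
    sample_thin: int = 10,
    restarts: int = 1,
) -> ATTModel:
    """Run the collapsed Gibbs sampler and return point estimates.

    With ``restarts > 1`` the chain is run from that many seeded random
    initializations and the one ending at the highest collapsed joint
    log-likelihood is kept — the usual guard against a chain settling in
    a poor mode.

    The asymmetric prior is re-optimized every ``optimize_interval``
    sweeps once ``burn_in`` sweeps have passed.  By default point
    estimates come from the final sample: theta = (n_ak + alpha)/(N_a +
    sum alpha), smoothed phi = (n_kw + beta)/(n_k + V beta), raw phi =
    n_kw/n_k with exact zeros.  With ``average_samples = S`` the
    estimates are instead averaged over the last S post-burn-in samples
    taken every ``sample_thin`` sweeps (labels are tied across samples by
    the shared state, so no alignment is needed); averaging reduces the
    Monte-Carlo noise of a single draw at the cost of slightly blurring
    the exact zeros of raw phi (a gene keeps probability zero only if it
    was unassigned in every averaged sample).  The collapsed joint
    log-likelihood is recorded every ``loglik_every`` sweeps for
    convergence monitoring.
    """
    if restarts > 1:
        restart_seeds = [
            int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed).generate_state(restarts)
        ]
        candidates = [
            train(
                corpus, K, iterations=iterations, burn_in=burn_in,
                optimize_interval=optimize_interval, alpha0=alpha0, beta0=beta0,
                seed=rs, optimize_hyper=optimize_hyper, loglik_every=loglik_every,
                average_samples=average_samples, sample_thin=sample_thin, restarts=1,
            )
            for rs in restart_seeds
        ]
        return max(candidates, key=lambda m: m.final_loglik)

    state = initialize_state(corpus, K, alpha0=alpha0, beta0=beta0, seed=seed)
    trace = []
    sample_sweeps: set[int] = set()
    if average_samples > 0:
        sample_sweeps = {
            iterations - i * sample_thin for i in range(average_samples)
        }
        if min(sample_sweeps) <= max(burn_in, 0):
            raise ValueError("averaged samples would fall inside the burn-in")
    theta_acc = phi_s_acc = phi_r_acc = None
    n_acc = 0
    for sweep_idx in range(1, iterations + 1):
        gibbs_sweep(state)
        if (
            optimize_hyper
            and sweep_idx > burn_in
            and optimize_interval > 0
            and sweep_idx % optimize_interval == 0
        ):
            optimize_alpha(state)
        if loglik_every > 0 and sweep_idx % loglik_every == 0:
            trace.append(joint_log_likelihood(state))
        if sweep_idx in sample_sweeps:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, ps, pr = (
                    estimate_theta(state),
                    estimate_phi(state, smoothed=True),
                    estimate_phi(state, smoothed=False),
                )
            if theta_acc is None:
                theta_acc, phi_s_acc, phi_r_acc = t, ps, pr
            else:
                theta_acc += t
                phi_s_acc += ps
                phi_r_acc += pr
            n_acc += 1

    if n_acc:
        theta = theta_acc / n_acc
        phi_smoothed = phi_s_acc / n_acc
        phi_raw = phi_r_acc / n_acc
        # renormalize raw rows in case an empty topic appeared in some sample
        raw_sums = phi_raw.sum(axis=1, keepdims=True)
        phi_raw = np.divide(phi_raw, np.where(raw_sums == 0, 1.0, raw_sums))
    else:
        theta = estimate_theta(state)
        phi_smoothed = estimate_phi(state, smoothed=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phi_raw = estimate_phi(state, smoothed=False)
    model = ATTModel(
        theta=theta,
        phi_smoothed=phi_smoothed,
        phi_raw=phi_raw,
        hyper=state.hyper,
        author_ids=list(corpus.author_ids),
        vocabulary=list(corpus.vocabulary),
        feature_level=corpus.feature_level,
        loglik=np.asarray(trace),
        seed=int(seed),
        iterations=int(iterations),
        empty_topics=state.n_k == 0,
        final_loglik=joint_log_likelihood(state),
    )
    model.validate()
    return model


def held_out_perplexity(
    model: ATTModel,
    heldout: CountCorpus,
    fold_in_sweeps: int = 100,
    seed: int = 0,
    method: str = "fold_in",
) -> float:
    """Held-out perplexity ``exp(-mean token log-likelihood)``.

    ``method="fold_in"`` infers each held-out document's topic weights by
    Gibbs sampling over all its tokens with the topic-gene distributions
    frozen at ``phi_smoothed`` and scores those same tokens — the
    simplest protocol, but biased toward larger K because theta adapts to
    the scored tokens.  ``method="completion"`` (document completion)
    infers theta from a seeded half of each document's tokens and scores
    only the other half, which makes perplexity comparable across K and
    is what model selection uses.  Held-out genes missing from the
    training vocabulary are dropped with a warning.
    """
    if heldout.n_docs == 0 or heldout.n_tokens == 0:
        raise ValueError("held-out corpus is empty")
    if method not in ("fold_in", "completion"):
        raise ValueError(f"unknown perplexity method {method!r}")
    vocab_index = {g: j for j, g in enumerate(model.vocabulary)}
    tok_doc, tok_word, _ = heldout.token_arrays()
    mapped = np.array([vocab_index.get(heldout.vocabulary[w], -1) for w in tok_word])
    oov = mapped < 0
    if np.any(oov):
        warnings.warn(f"dropping {int(oov.sum())} out-of-vocabulary held-out token(s)")
        tok_doc = tok_doc[~oov]
        mapped = mapped[~oov]
    if mapped.size == 0:
        raise ValueError("no held-out tokens remain after vocabulary mapping")

    K = model.hyper.K
    alpha = model.hyper.alpha
    rng = np.random.default_rng(seed)

    if method == "completion":
        est_mask = np.zeros(mapped.shape[0], dtype=bool)
        for d in np.unique(tok_doc):
            idx = np.nonzero(tok_doc == d)[0]
            take = max(1, len(idx) // 2) if len(idx) > 1 else 0
            est_mask[rng.permutation(idx)[:take]] = True
        if not np.any(~est_mask):
            raise ValueError("no evaluation tokens left after the completion split")
    else:
        est_mask = np.ones(mapped.shape[0], dtype=bool)

    fit_doc, fit_word = tok_doc[est_mask], mapped[est_mask]
    n_dk = np.zeros((heldout.n_docs, K), dtype=np.int64)
    if fit_word.size:
        z = rng.integers(0, K, size=fit_word.shape[0]).astype(np.int64)
        np.add.at(n_dk, (fit_doc, z), 1)
        for _ in range(fold_in_sweeps):
            u = rng.random(fit_word.shape[0])
            _gibbs.fold_in_sweep(z, fit_word, fit_doc, n_dk, model.phi_smoothed, alpha, u)
    theta_d = (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + alpha.sum())

    if method == "completion":
        eval_doc, eval_word = tok_doc[~est_mask], mapped[~est_mask]
    else:
        eval_doc, eval_word = tok_doc, mapped
    tok_prob = np.einsum("ik,ik->i", theta_d[eval_doc], model.phi_smoothed[:, eval_word].T)
    return float(np.exp(-np.mean(np.log(tok_prob))))


@dataclass
class TopicSelection:
    """Cross-validated perplexity per candidate K, plus the argmin."""

    table: pd.DataFrame  # columns: K, mean_perplexity, sd_perplexity
    recommended_K: int


def select_num_topics(
    corpus: CountCorpus,
    K_grid: list[int],
    folds: int = 10,
    train_kwargs: dict | None = None,
    fold_in_sweeps: int = 100,
    seed: int = 0,
    method: str = "completion",
) -> TopicSelection:
    """Choose the number of latent processes by K-fold held-out perplexity.

    Documents are partitioned into ``folds`` seeded folds; for each K the
    model is refitted on the training folds and held-out perplexity
    measured on the left-out fold, by document completion by default (the
    protocol that is unbiased across K; see ``held_out_perplexity``).
    The recommendation is the argmin of the mean, with ties broken toward
    smaller K (parsimony).
    """
    if not K_grid:
        raise ValueError("K_grid must not be empty")
    if corpus.n_docs < folds:
        raise ValueError("need at least as many documents as folds")
    train_kwargs = dict(train_kwargs or {})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(corpus.n_docs)
    fold_of_doc = np.arange(corpus.n_docs) % folds
    fold_assign = np.empty(corpus.n_docs, dtype=np.int64)
    fold_assign[perm] = fold_of_doc

    rows = []
    for K in sorted(K_grid):
        perps = []
        for f in range(folds):
            train_idx = np.nonzero(fold_assign != f)[0]
            test_idx = np.nonzero(fold_assign == f)[0]
            sub = corpus.subset_docs(train_idx)
            held = corpus.subset_docs(test_idx)
            fit_seed = int(rng.integers(0, 2**31 - 1))
            model = train(sub, K=K, seed=fit_seed, **train_kwargs)
            perps.append(
                held_out_perplexity(
                    model, held, fold_in_sweeps=fold_in_sweeps, seed=fit_seed + 1,
                    method=method,
                )
            )
        rows.append((K, float(np.mean(perps)), float(np.std(perps, ddof=1))))
        logger.info("K=%d: mean held-out perplexity %.3f", K, rows[-1][1])

    table = pd.DataFrame(rows, columns=["K", "mean_perplexity", "sd_perplexity"])
    best = int(table.loc[table["mean_perplexity"].idxmin(), "K"])  # sorted grid: ties -> smaller K
    return TopicSelection(table=table, recommended_K=best)
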