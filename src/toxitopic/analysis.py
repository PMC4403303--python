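"""Feature similarity and latent-process reporting.

Similarity between two features (treatments, drugs, or dose-time pairs)
is the symmetric Kullback-Leibler divergence between their latent-process
distributions P(Z|feature):

    sKL(p, q) = sum_k [ p_k ln(p_k / q_k) + q_k ln(q_k / p_k) ]

in nats; low scores mean similar latent-process usage.  sKL is a
symmetric premetric (non-negative, zero iff equal) but does not satisfy
the triangle inequality.  Scores are finite only for strictly positive
distributions, so they are always computed on the alpha-smoothed theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from toxitopic.att import ATTModel

logger = logging.getLogger(__name__)


def skl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric KL divergence KL(p||q) + KL(q||p) in nats."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
        if np.any(v <= 0):
            raise ValueError(
                f"{name} has zero/negative components; use the smoothed theta "
                "(strictly positive under the Dirichlet prior)"
            )
    return float(rel_entr(p, q).sum() + rel_entr(q, p).sum())


@dataclass
class SimilarityMatrix:
    """Pairwise sKL scores between features; zero diagonal, symmetric."""

    scores: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.feature_ids), len(self.feature_ids)):
            raise ValueError("scores shape must match feature_ids")
        if not np.allclose(s, s.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.diag(s) != 0):
            raise ValueError("similarity matrix diagonal must be zero")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("sKL scores must be non-negative and finite")
        self.scores = s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.feature_ids, columns=self.feature_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        return cls(df.to_numpy(), [str(f) for f in df.index])


def pairwise_skl(theta: np.ndarray, feature_ids: list[str]) -> SimilarityMatrix:
    """All-pairs sKL between the rows of a (smoothed) theta matrix."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta rows must be strictly positive; use the smoothed theta")
    log_t = np.log(theta)
    self_term = np.sum(theta * log_t, axis=1)  # sum_k p ln p
    cross = theta @ log_t.T  # cross[i, j] = sum_k p_i ln p_j
    kl = self_term[:, None] - cross
    scores = kl + kl.T
    np.fill_diagonal(scores, 0.0)
    scores = np.maximum(0.5 * (scores + scores.T), 0.0)
    return SimilarityMatrix(scores=scores, feature_ids=list(feature_ids))


def rank_similar(
    sim: SimilarityMatrix, feature_id: str, top_n: int = 10
) -> list[tuple[str, float]]:
    """Most similar features in ascending sKL order, self excluded; ties
    broken by feature-id lexicographic order."""
    if feature_id not in sim.feature_ids:
        raise KeyError(f"unknown feature {feature_id!r}")
    i = sim.feature_ids.index(feature_id)
    others = [
        (other, float(sim.scores[i, j]))
        for j, other in enumerate(sim.feature_ids)
        if j != i
    ]
    others.sort(key=lambda t: (t[1], t[0]))
    return others[: max(top_n, 0)]


def top_topics(
    theta: np.ndarray,
    feature_ids: list[str],
    feature_id: str,
    n: int = 3,
) -> list[tuple[int, float]]:
    """The n most probable latent processes for a feature, descending;
    ties broken toward the smaller process index."""
    if feature_id not in feature_ids:
        raise KeyError(f"unknown feature {feature_id!r}")
    row = np.asarray(theta)[feature_ids.index(feature_id)]
    K = row.shape[0]
    if n > K:
        logger.warning("requested %d topics but model has only %d", n, K)
        n = K
    order = np.lexsort((np.arange(K), -row))
    return [(int(k), float(row[k])) for k in order[:n]]


def top_genes(
    phi_raw: np.ndarray,
    vocabulary: list[str],
    topic: int,
    max_n: int | None = None,
) -> list[tuple[str, float]]:
    """Genes with strictly positive raw probability in one latent process,
    descending; ties broken by gene identifier.  Empty processes give an
    empty list."""
    if not 0 <= topic < phi_raw.shape[0]:
        raise IndexError(f"topic {topic} out of range")
    row = np.asarray(phi_raw)[topic]
    support = np.nonzero(row > 0)[0]
    ranked = sorted(
        ((vocabulary[j], float(row[j])) for j in support),
        key=lambda t: (-t[1], t[0]),
    )
    if max_n is not None:
        ranked = ranked[:max_n]
    return ranked


def export_gene_lists(
    model: ATTModel,
    out_dir: str | Path,
    topics: list[int] | None = None,
) -> Path:
    """One plain-text gene list per latent process (one gene ID per line),
    ready for upload to annotation services such as DAVID, plus a
    manifest mapping process -> filename."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chosen = list(topics) if topics is not None else list(range(model.hyper.K))
    manifest_rows = []
    for k in chosen:
        genes = top_genes(model.phi_raw, model.vocabulary, k)
        fname = f"topic_{k}.txt"
        (out / fname).write_text("".join(g + "\n" for g, _ in genes))
        manifest_rows.append((k, fname, len(genes), len(genes) == 0))
    pd.DataFrame(
        manifest_rows, columns=["topic", "filename", "n_genes", "empty"]
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Standard GMT gene-set file: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def enrich_gene_sets(
    gene_list: list[str],
    gene_sets: dict[str, list[str]],
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    Upper-tail p-value P(X >= overlap) for drawing ``len(gene_list)``
    genes from a universe of ``universe_size`` containing the set; FDR by
    Benjamini-Hochberg across sets.  A local stand-in for web annotation
    services; p-values are not comparable to DAVID's EASE score.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    if universe_size < len(gene_list):
        raise ValueError("universe_size must be at least the gene-list size")
    query = set(gene_list)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        overlap = len(query & members)
        p = float(hypergeom.sf(overlap - 1, universe_size, len(members), len(query)))
        rows.append((name, overlap, len(members), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p_value"])
    df["fdr_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "gene_set"], kind="stable").reset_index(drop=True)
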