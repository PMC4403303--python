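"""Discrete "document-word" corpus for author-topic inference.

Documents are treatments (unique drug-dose-time combinations), words are
genes, and token counts are discretized absolute fold changes.  Each
document is written by exactly one author; the author is the treatment
itself, its drug, or its dose-time pair depending on the feature level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

FEATURE_LEVELS = ("treatment", "drug", "time_dose")


@dataclass
class CountCorpus:
    """Sparse document x gene token counts with a document-to-author map.

    Parameters
    ----------
    counts
        ``(n_docs, n_vocab)`` sparse integer matrix of token counts.
    vocabulary
        Gene identifiers, one per column.
    doc_ids
        Document (treatment) keys, one per row.
    doc_author
        For each document, the index of its author in ``author_ids``.
    author_ids
        Author identifiers (treatment keys, drug names, or dose-time keys).
    feature_level
        One of ``{"treatment", "drug", "time_dose"}``.
    """

    counts: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]
    doc_author: np.ndarray
    author_ids: list[str]
    feature_level: str = "treatment"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.doc_author = np.asarray(self.doc_author, dtype=np.int64)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.feature_level not in FEATURE_LEVELS:
            raise ValueError(f"unknown feature_level {self.feature_level!r}")
        n_docs, n_vocab = self.counts.shape
        if len(self.doc_ids) != n_docs:
            raise ValueError("doc_ids length does not match count matrix")
        if len(self.vocabulary) != n_vocab:
            raise ValueError("vocabulary length does not match count matrix")
        if self.doc_author.shape != (n_docs,):
            raise ValueError("doc_author must map every document to one author")
        if n_docs and (self.doc_author.min() < 0 or self.doc_author.max() >= len(self.author_ids)):
            raise ValueError("doc_author indexes outside author_ids")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        totals = np.asarray(self.counts.sum(axis=1)).ravel()
        if np.any(totals < 1):
            empty = [self.doc_ids[i] for i in np.nonzero(totals < 1)[0]]
            raise ValueError(f"documents with zero tokens: {empty}")
        if self.feature_level == "treatment" and len(self.author_ids) != n_docs:
            raise ValueError("at treatment level author count must equal document count")

    # -- basic properties ----------------------------------------------
    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.counts.shape[1]

    @property
    def n_authors(self) -> int:
        return len(self.author_ids)

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())

    def token_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten counts into per-token (doc, word, author) index arrays.

        Token order is document order, then vocabulary order within each
        document — the order the Gibbs sweep visits tokens.
        """
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        rows = coo.row[order]
        cols = coo.col[order]
        reps = coo.data[order].astype(np.int64)
        tok_doc = np.repeat(rows, reps).astype(np.int64)
        tok_word = np.repeat(cols, reps).astype(np.int64)
        tok_author = self.doc_author[tok_doc]
        return tok_doc, tok_word, tok_author

    def subset_docs(self, doc_indices: np.ndarray) -> "CountCorpus":
        """Corpus restricted to the given documents (vocabulary kept whole).

        Authors without remaining documents are dropped and the author map
        re-indexed; at treatment level this is just row selection.
        """
        doc_indices = np.asarray(doc_indices, dtype=np.int64)
        counts = self.counts[doc_indices]
        doc_ids = [self.doc_ids[i] for i in doc_indices]
        old_auth = self.doc_author[doc_indices]
        kept = np.unique(old_auth)
        remap = {int(a): i for i, a in enumerate(kept)}
        return CountCorpus(
            counts=counts,
            vocabulary=list(self.vocabulary),
            doc_ids=doc_ids,
            doc_author=np.array([remap[int(a)] for a in old_auth], dtype=np.int64),
            author_ids=[self.author_ids[int(a)] for a in kept],
            feature_level=self.feature_level,
        )

    # -- on-disk format -------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        """Write the corpus as a directory of plain-text tables.

        ``counts.tsv`` holds (doc_id, gene, count) triples, ``vocab.txt``
        one gene per line, ``authors.tsv`` the doc -> author map plus the
        feature level in a header comment.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(out / "counts.tsv", "w") as fh:
            fh.write("doc_id\tgene\tcount\n")
            for i in order:
                fh.write(f"{self.doc_ids[coo.row[i]]}\t{self.vocabulary[coo.col[i]]}\t{int(coo.data[i])}\n")
        (out / "vocab.txt").write_text("".join(g + "\n" for g in self.vocabulary))
        with open(out / "authors.tsv", "w") as fh:
            fh.write(f"# feature_level={self.feature_level}\n")
            fh.write("# author_order=" + "\t".join(self.author_ids) + "\n")
            fh.write("doc_id\tauthor_id\n")
            for d, a in zip(self.doc_ids, self.doc_author):
                fh.write(f"{d}\t{self.author_ids[int(a)]}\n")
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "CountCorpus":
        in_dir = Path(in_dir)
        vocabulary = (in_dir / "vocab.txt").read_text().splitlines()
        vocab_index = {g: j for j, g in enumerate(vocabulary)}

        feature_level = "treatment"
        doc_ids: list[str] = []
        doc_seen: dict[str, int] = {}
        author_ids: list[str] = []
        author_seen: dict[str, int] = {}
        doc_author_list: list[int] = []
        with open(in_dir / "authors.tsv") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "feature_level=" in line:
                        feature_level = line.split("feature_level=")[1].strip()
                    elif "author_order=" in line:
                        author_ids = line.split("author_order=")[1].split("\t")
                        author_seen = {a: i for i, a in enumerate(author_ids)}
                    continue
                if line == "doc_id\tauthor_id" or not line:
                    continue
                doc_id, author_id = line.split("\t")
                doc_seen[doc_id] = len(doc_ids)
                doc_ids.append(doc_id)
                if author_id not in author_seen:
                    author_seen[author_id] = len(author_ids)
                    author_ids.append(author_id)
                doc_author_list.append(author_seen[author_id])

        rows, cols, vals = [], [], []
        with open(in_dir / "counts.tsv") as fh:
            header = fh.readline()
            assert header.startswith("doc_id")
            for line in fh:
                doc_id, gene, count = line.rstrip("\n").split("\t")
                rows.append(doc_seen[doc_id])
                cols.append(vocab_index[gene])
                vals.append(int(count))
        counts = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(doc_ids), len(vocabulary)), dtype=np.int64
        )
        return cls(
            counts=counts,
            vocabulary=vocabulary,
            doc_ids=doc_ids,
            doc_author=np.array(doc_author_list, dtype=np.int64),
            author_ids=author_ids,
            feature_level=feature_level,
        )
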