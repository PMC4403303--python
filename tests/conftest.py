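import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from toxitopic.corpus import CountCorpus
from toxitopic.preprocess import ExpressionStudy


def corpus_from_dense(
    counts, feature_level="treatment", doc_author=None, author_ids=None
) -> CountCorpus:
    counts = np.asarray(counts)
    n_docs, n_vocab = counts.shape
    if doc_author is None:
        doc_author = np.arange(n_docs)
    if author_ids is None:
        author_ids = (
            [f"doc{d}" for d in range(n_docs)]
            if feature_level == "treatment"
            else [f"author{a}" for a in sorted(set(map(int, doc_author)))]
        )
    return CountCorpus(
        counts=sp.csr_matrix(counts),
        vocabulary=[f"g{j}" for j in range(n_vocab)],
        doc_ids=[f"doc{d}" for d in range(n_docs)],
        doc_author=np.asarray(doc_author),
        author_ids=author_ids,
        feature_level=feature_level,
    )


def study_from_group_means(gene_means: dict[str, dict[str, float]]) -> ExpressionStudy:
    """Build a two-replicate study whose per-group means are exactly the
    given values.  ``gene_means[gene][group]`` with groups like
    ``DRUGA|low|3`` (treated) and ``DRUGA|control|3``.
    """
    genes = sorted(gene_means)
    groups = sorted({grp for g in gene_means.values() for grp in g})
    cols, meta_rows = {}, []
    for grp in groups:
        drug, dose, time = grp.split("|")
        for r, offset in enumerate((-0.25, 0.25)):
            sid = f"{grp.replace('|', '_')}_r{r}"
            cols[sid] = [gene_means[g][grp] + offset for g in genes]
            meta_rows.append((sid, drug, dose, int(time), dose == "control"))
    intensities = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "drug", "dose", "time_days", "is_control"]
    )
    return ExpressionStudy(intensities, meta)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """One drug, two doses at day 3, exact group means.

    Planted fold changes vs the control mean of 2.0:
      g1: low 1.5 (at threshold), middle 2.5
      g2: low -2.0, middle -4.0 (treated means 1.0 and 0.5)
      g3: unchanged (FC 1.0)
      g4: low 4.0, middle 1.25
    """
    return study_from_group_means(
        {
            "g1": {"DRUGA|control|3": 2.0, "DRUGA|low|3": 3.0, "DRUGA|middle|3": 5.0},
            "g2": {"DRUGA|control|3": 2.0, "DRUGA|low|3": 1.0, "DRUGA|middle|3": 0.5},
            "g3": {"DRUGA|control|3": 2.0, "DRUGA|low|3": 2.0, "DRUGA|middle|3": 2.0},
            "g4": {"DRUGA|control|3": 2.0, "DRUGA|low|3": 8.0, "DRUGA|middle|3": 2.5},
        }
    )
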