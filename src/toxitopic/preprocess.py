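"""From treated/control intensities to an authored count corpus.

The preprocessing chain mirrors standard toxicogenomics practice for
repeated-dose designs (drug x {low, middle, high} x {3, 7, 14, 28} days
with concurrent controls):

1. per-treatment fold changes against the matching control group, stored
   with the reciprocal-signed convention (``-k`` means ``k``-fold down);
2. a pure fold-change DEG filter (|FC| > 1.5 by default), zeroing
   everything else;
3. discretization of surviving |FC| values to integer token counts;
4. optional regrouping of the treatment documents under drug or
   dose-time authors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from toxitopic.corpus import CountCorpus

logger = logging.getLogger(__name__)

DOSE_LEVELS = ("low", "middle", "high")
TIME_POINTS = (3, 7, 14, 28)


def make_treatment_key(drug: str, dose: str, time_days: int | float) -> str:
    """Canonical treatment key, e.g. ``ACETAMINOPHEN|middle|3d``."""
    t = int(time_days) if float(time_days) == int(time_days) else float(time_days)
    return f"{drug}|{dose}|{t}d"


def parse_treatment_key(key: str) -> tuple[str, str, float]:
    try:
        drug, dose, time_s = key.split("|")
        if not time_s.endswith("d"):
            raise ValueError
        return drug, dose, float(time_s[:-1])
    except ValueError:
        raise ValueError(f"malformed treatment key {key!r}; expected 'DRUG|DOSE|TIMEd'") from None


@dataclass
class ExpressionStudy:
    """Per-sample intensities plus the sample -> (drug, dose, time) map.

    ``intensities`` is a genes x samples DataFrame of positive expression
    values (arbitrary units, assumed pre-normalized).  ``sample_meta`` has
    one row per sample with columns ``sample_id``, ``drug``, ``dose``
    (``low``/``middle``/``high``/``control``, case-insensitive),
    ``time_days`` and ``is_control``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta.copy()
        meta["dose"] = meta["dose"].astype(str).str.lower()
        if "is_control" not in meta.columns:
            meta["is_control"] = meta["dose"] == "control"
        meta["is_control"] = meta["is_control"].astype(bool)
        meta["sample_id"] = meta["sample_id"].astype(str)
        self.sample_meta = meta
        self.validate()

    def validate(self) -> None:
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][:5]
            raise ValueError(f"duplicate gene identifiers: {list(dup)}")
        missing = set(self.sample_meta["sample_id"]) - set(map(str, self.intensities.columns))
        if missing:
            raise ValueError(f"samples in metadata but not in the matrix: {sorted(missing)[:5]}")
        bad_dose = set(self.sample_meta.loc[~self.sample_meta["is_control"], "dose"]) - set(DOSE_LEVELS)
        if bad_dose:
            raise ValueError(f"unknown treated dose levels: {sorted(bad_dose)}")
        vals = self.intensities[self.sample_meta["sample_id"]].to_numpy()
        if not np.all(vals > 0):
            g, s = np.argwhere(~(vals > 0))[0]
            raise ValueError(
                f"non-positive intensity for gene {self.intensities.index[g]!r} "
                f"in sample {self.sample_meta['sample_id'].iloc[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.intensities.index)

    def treatments(self) -> pd.DataFrame:
        """Unique treated (drug, dose, time_days) combinations."""
        treated = self.sample_meta.loc[~self.sample_meta["is_control"]]
        return treated[["drug", "dose", "time_days"]].drop_duplicates().reset_index(drop=True)


@dataclass
class FoldChangeMatrix:
    """Signed fold changes, genes x treatments.

    Values follow the reciprocal-signed convention: ``r`` if the treated
    mean is ``r``-fold above control (``r >= 1``), ``-1/r``-style ``-k``
    if ``k``-fold below; 0 marks a filtered (non-DEG) entry, and no value
    lies strictly inside (-1, 1) except exactly 0.
    """

    values: pd.DataFrame  # genes x treatment keys

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index=None, columns=None)
        self.validate()

    def validate(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate treatment keys")
        v = self.values.to_numpy()
        inside = (np.abs(v) < 1.0) & (v != 0.0)
        if np.any(inside):
            raise ValueError("fold-change magnitudes must be >= 1 (or exactly 0)")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def treatments(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FoldChangeMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def compute_fold_changes(
    study: ExpressionStudy, replicate_mean: str = "arithmetic"
) -> FoldChangeMatrix:
    """Per-treatment signed fold changes against concurrent controls.

    For each unique (drug, dose, time) treatment the treated replicate
    intensities are averaged per gene, as are the control replicates
    matched on (drug, time); the ratio ``r = treated / control`` is stored
    as ``r`` when ``r >= 1`` and as ``-1/r`` otherwise, so the magnitude is
    ``max(r, 1/r)`` and the sign carries the direction.

    Parameters
    ----------
    replicate_mean
        ``"arithmetic"`` (default) or ``"geometric"`` averaging of
        replicate intensities before the ratio.
    """
    if replicate_mean not in ("arithmetic", "geometric"):
        raise ValueError("replicate_mean must be 'arithmetic' or 'geometric'")

    meta = study.sample_meta
    expr = study.intensities

    def group_mean(sample_ids: pd.Series) -> np.ndarray:
        block = expr[list(sample_ids)].to_numpy(dtype=float)
        if replicate_mean == "geometric":
            return np.exp(np.mean(np.log(block), axis=1))
        return block.mean(axis=1)

    controls = meta.loc[meta["is_control"]]
    treated = meta.loc[~meta["is_control"]]
    if treated.empty:
        raise ValueError("study has no treated samples")

    columns: dict[str, np.ndarray] = {}
    for (drug, dose, time_days), grp in treated.groupby(
        ["drug", "dose", "time_days"], sort=True
    ):
        key = make_treatment_key(drug, dose, time_days)
        ctrl = controls.loc[
            (controls["drug"] == drug) & (controls["time_days"] == time_days)
        ]
        if ctrl.empty:
            raise ValueError(f"treatment {key!r} has no matching control samples")
        r = group_mean(grp["sample_id"]) / group_mean(ctrl["sample_id"])
        signed = np.where(r >= 1.0, r, -1.0 / r)
        columns[key] = signed

    values = pd.DataFrame(columns, index=expr.index)
    return FoldChangeMatrix(values)


def apply_deg_filter(fc: FoldChangeMatrix, threshold: float = 1.5) -> FoldChangeMatrix:
    """Zero every entry whose magnitude is not strictly above ``threshold``.

    The cutoff is strict: a magnitude exactly equal to the threshold is
    treated as not differentially expressed.  Idempotent.
    """
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1 (fold-change magnitudes are >= 1)")
    v = fc.values.to_numpy(copy=True)
    v[np.abs(v) <= threshold] = 0.0
    return FoldChangeMatrix(pd.DataFrame(v, index=fc.values.index, columns=fc.values.columns))


def discretize_to_counts(
    fc: FoldChangeMatrix, scale: float = 1.0, signed_tokens: bool = False
) -> CountCorpus:
    """Turn filtered fold changes into gene token counts, one document per
    treatment.

    Token count = ``round(scale * |FC|)`` (half-to-even) for nonzero
    entries, 0 otherwise.  Documents left with zero total count are
    dropped with a logged warning.  With ``signed_tokens`` the vocabulary
    splits each gene into ``GENE__up`` / ``GENE__dn`` entries so direction
    survives discretization (off by default).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    v = fc.values.to_numpy()
    counts = np.rint(scale * np.abs(v)).astype(np.int64)
    counts[v == 0.0] = 0

    genes = fc.genes
    if signed_tokens:
        up = np.where(v > 0, counts, 0)
        dn = np.where(v < 0, counts, 0)
        mat = np.concatenate([up, dn], axis=0)  # (2G) x T
        vocabulary = [f"{g}__up" for g in genes] + [f"{g}__dn" for g in genes]
    else:
        mat = counts
        vocabulary = list(genes)

    doc_totals = mat.sum(axis=0)
    keep = doc_totals >= 1
    dropped = [t for t, k in zip(fc.treatments, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d zero-token treatment document(s): %s", len(dropped), dropped
        )
    doc_ids = [t for t, k in zip(fc.treatments, keep) if k]
    if not doc_ids:
        raise ValueError("no treatment document has any tokens after filtering")

    counts_dw = sp.csr_matrix(mat[:, keep].T)
    return CountCorpus(
        counts=counts_dw,
        vocabulary=vocabulary,
        doc_ids=doc_ids,
        doc_author=np.arange(len(doc_ids), dtype=np.int64),
        author_ids=list(doc_ids),
        feature_level="treatment",
    )


def regroup_by_feature(corpus: CountCorpus, feature_level: str) -> CountCorpus:
    """Re-author the treatment documents at a coarser feature level.

    ``drug`` assigns each treatment document to its drug; ``time_dose`` to
    its (dose, time) pair (e.g. 3 doses x 4 durations -> 12 authors);
    ``treatment`` restores the identity map.  Documents and counts are
    untouched, so total token mass is conserved.
    """
    if feature_level not in ("treatment", "drug", "time_dose"):
        raise ValueError(f"unknown feature_level {feature_level!r}")
    parsed = [parse_treatment_key(d) for d in corpus.doc_ids]
    if feature_level == "treatment":
        author_of_doc = list(corpus.doc_ids)
    elif feature_level == "drug":
        author_of_doc = [drug for drug, _, _ in parsed]
    else:
        author_of_doc = [
            make_treatment_key("", dose, time)[1:] for _, dose, time in parsed
        ]  # "DOSE|TIMEd"
    author_ids = sorted(set(author_of_doc))
    index = {a: i for i, a in enumerate(author_ids)}
    return CountCorpus(
        counts=corpus.counts.copy(),
        vocabulary=list(corpus.vocabulary),
        doc_ids=list(corpus.doc_ids),
        doc_author=np.array([index[a] for a in author_of_doc], dtype=np.int64),
        author_ids=author_ids,
        feature_level=feature_level,
    )


# -- tabular I/O -------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    return df


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, drug, dose, time_days, is_control."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "drug", "dose", "time_days"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


def load_study(expr_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    return ExpressionStudy(read_expression(expr_path), read_sample_metadata(meta_path))
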