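"""Ground-truth generators for the author-topic pipeline.

Two generators: ``simulate_att_corpus`` samples directly from the
author-topic generative model (the process the collapsed Gibbs sampler
inverts), and ``simulate_tg_study`` emulates a repeated-dose
toxicogenomics study — a drugs x {low, middle, high} x {3, 7, 14, 28}
day factorial with concurrent controls, planted co-regulated gene
modules whose fold changes depend on drug, dose, and time, and
multiplicative replicate noise.

Module fold-change profiles are specified on the log2 scale (dose and
time act multiplicatively on log2 FC), so penetration of the 1.5 DEG
cutoff is predictable.  The generators capture the statistical structure
the analysis assumes, not microarray physics (no probe effects or
saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from toxitopic.corpus import CountCorpus
from toxitopic.preprocess import DOSE_LEVELS, TIME_POINTS, ExpressionStudy, make_treatment_key


@dataclass
class PlantedTruth:
    """Ground truth behind a simulated corpus or study."""

    true_phi: np.ndarray | None = None  # topic x gene
    true_theta: np.ndarray | None = None  # author x topic
    true_alpha: np.ndarray | None = None
    design: pd.DataFrame | None = None  # treatment metadata
    effect_map: dict | None = None  # module -> activation profile
    module_genes: dict | None = None  # module -> gene list


def simulate_att_corpus(
    K: int,
    V: int,
    n_authors: int,
    docs_per_author: int,
    tokens_per_doc: int,
    alpha: np.ndarray,
    beta: float,
    seed: int = 0,
) -> tuple[CountCorpus, PlantedTruth]:
    """Ancestral sample from the author-topic generative model.

    Topics are drawn from a symmetric Dirichlet(beta) over the V genes,
    per-author topic weights from Dirichlet(alpha), and each token by
    topic-then-gene sampling.  Reproducible under a fixed seed.
    """
    alpha = np.asarray(alpha, dtype=float)
    if min(K, V, n_authors, docs_per_author, tokens_per_doc) < 1:
        raise ValueError("all sizes must be >= 1")
    if alpha.shape != (K,) or np.any(alpha <= 0) or beta <= 0:
        raise ValueError("alpha must be K positive reals and beta > 0")

    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, beta), size=K)
    theta = rng.dirichlet(alpha, size=n_authors)

    n_docs = n_authors * docs_per_author
    counts = np.zeros((n_docs, V), dtype=np.int64)
    doc_author = np.repeat(np.arange(n_authors), docs_per_author)
    for d in range(n_docs):
        zs = rng.choice(K, size=tokens_per_doc, p=theta[doc_author[d]])
        for k, nk in zip(*np.unique(zs, return_counts=True)):
            ws = rng.choice(V, size=nk, p=phi[k])
            np.add.at(counts[d], ws, 1)

    vocabulary = [f"G{j:04d}" for j in range(V)]
    corpus = CountCorpus(
        counts=sp.csr_matrix(counts),
        vocabulary=vocabulary,
        doc_ids=[f"doc{d:04d}" for d in range(n_docs)],
        doc_author=doc_author,
        author_ids=[f"author{a:03d}" for a in range(n_authors)],
        feature_level="treatment" if docs_per_author == 1 else "drug",
    )
    truth = PlantedTruth(true_phi=phi, true_theta=theta, true_alpha=alpha.copy())
    return corpus, truth


@dataclass
class PlantedModule:
    """A co-regulated gene module with a drug/dose/time activation profile.

    log2 fold change of a member gene under (drug, dose, time) is
    ``log2_amplitude * dose_weights[dose] * time_weights[time]`` when the
    drug is affected, 0 otherwise.  Flat (all-1) weights by default.
    """

    name: str
    genes: list[str]
    drugs: list[str]
    dose_weights: dict[str, float] = field(
        default_factory=lambda: {d: 1.0 for d in DOSE_LEVELS}
    )
    time_weights: dict[int, float] = field(
        default_factory=lambda: {t: 1.0 for t in TIME_POINTS}
    )
    log2_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.name!r} has no genes")

    def log2_fc(self, drug: str, dose: str, time: int) -> float:
        if drug not in self.drugs:
            return 0.0
        return self.log2_amplitude * self.dose_weights[dose] * self.time_weights[int(time)]


def reducibility_scenario(
    kind: str,
    drug: str,
    genes_a: list[str],
    genes_b: list[str],
    log2_amplitude: float = 2.0,
) -> list[PlantedModule]:
    """Two complementary modules giving a drug a dose- or time-driven
    latent-process mixture.

    ``"dose_driven"``: module A strengthens and module B weakens with
    dose while both are flat in time, so topic usage depends on dose
    only.  ``"time_driven"``: the same pattern along the time axis.
    """
    up = {"low": 0.6, "middle": 1.3, "high": 2.0}
    dn = {"low": 2.0, "middle": 1.3, "high": 0.6}
    t_up = {3: 0.6, 7: 1.1, 14: 1.6, 28: 2.2}
    t_dn = {3: 2.2, 7: 1.6, 14: 1.1, 28: 0.6}
    if kind == "dose_driven":
        return [
            PlantedModule(f"{drug}_A", genes_a, [drug], dose_weights=dict(up),
                          log2_amplitude=log2_amplitude),
            PlantedModule(f"{drug}_B", genes_b, [drug], dose_weights=dict(dn),
                          log2_amplitude=log2_amplitude),
        ]
    if kind == "time_driven":
        return [
            PlantedModule(f"{drug}_A", genes_a, [drug], time_weights=dict(t_up),
                          log2_amplitude=log2_amplitude),
            PlantedModule(f"{drug}_B", genes_b, [drug], time_weights=dict(t_dn),
                          log2_amplitude=log2_amplitude),
        ]
    raise ValueError(f"unknown scenario kind {kind!r}")


def simulate_tg_study(
    n_drugs: int = 5,
    n_genes: int = 500,
    modules: list[PlantedModule] | None = None,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionStudy, PlantedTruth]:
    """Repeated-dose factorial study with planted gene modules.

    Every drug is crossed with 3 doses and 4 durations (12 treatments per
    drug) and each (drug, time) has its own concurrent control group.
    Control intensities are log-normal around a per-gene baseline;
    treated intensities multiply module genes by 2**log2_fc; every
    replicate carries multiplicative log-normal noise with standard
    deviation ``noise_sd`` (natural-log scale, a realistic magnitude for
    combined biological and technical microarray variation).
    """
    if n_drugs < 1 or n_genes < 1 or n_replicates < 1:
        raise ValueError("n_drugs, n_genes and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{j:04d}" for j in range(n_genes)]
    gene_index = {g: j for j, g in enumerate(genes)}
    drugs = [f"DRUG{i + 1}" for i in range(n_drugs)]
    modules = list(modules or [])
    for m in modules:
        unknown = set(m.genes) - set(genes)
        if unknown:
            raise ValueError(f"module {m.name!r} references unknown genes: {sorted(unknown)[:5]}")
        bad_drugs = set(m.drugs) - set(drugs)
        if bad_drugs:
            raise ValueError(f"module {m.name!r} references unknown drugs: {sorted(bad_drugs)}")

    baseline = 2.0 ** rng.normal(8.0, 1.0, size=n_genes)

    sample_ids, columns, meta_rows = [], [], []

    def add_sample(sid: str, drug: str, dose: str, time: int, is_control: bool, log2fc: np.ndarray):
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_genes))
        columns.append(baseline * (2.0**log2fc) * noise)
        sample_ids.append(sid)
        meta_rows.append((sid, drug, dose, time, is_control))

    zero = np.zeros(n_genes)
    for drug, time in product(drugs, TIME_POINTS):
        for r in range(n_replicates):
            add_sample(f"{drug}_ctrl_{time}d_r{r}", drug, "control", time, True, zero)
        for dose in DOSE_LEVELS:
            log2fc = np.zeros(n_genes)
            for m in modules:
                fc = m.log2_fc(drug, dose, time)
                if fc != 0.0:
                    for g in m.genes:
                        log2fc[gene_index[g]] += fc
            for r in range(n_replicates):
                add_sample(f"{drug}_{dose}_{time}d_r{r}", drug, dose, time, False, log2fc)

    intensities = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "drug", "dose", "time_days", "is_control"]
    )
    study = ExpressionStudy(intensities, meta)

    design = pd.DataFrame(
        [
            (make_treatment_key(d, ds, t), d, ds, t)
            for d, ds, t in product(drugs, DOSE_LEVELS, TIME_POINTS)
        ],
        columns=["treatment", "drug", "dose", "time_days"],
    )
    true_phi = None
    if modules:
        true_phi = np.zeros((len(modules), n_genes))
        for i, m in enumerate(modules):
            for g in m.genes:
                true_phi[i, gene_index[g]] = 1.0 / len(m.genes)
    truth = PlantedTruth(
        true_phi=true_phi,
        design=design,
        effect_map={
            m.name: {
                "drugs": list(m.drugs),
                "dose_weights": dict(m.dose_weights),
                "time_weights": dict(m.time_weights),
                "log2_amplitude": m.log2_amplitude,
            }
            for m in modules
        },
        module_genes={m.name: list(m.genes) for m in modules},
    )
    return study, truth


def align_topics(
    estimated_phi: np.ndarray, true_phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve label switching between estimated and planted topics.

    Finds the one-to-one assignment of estimated to planted topics that
    minimizes the summed total-variation distance (Hungarian algorithm,
    exactly optimal for any K).  The estimated set may be larger than the
    planted one; surplus topics stay unmatched.  Returns the permutation
    (``perm[j]`` = estimated index matched to planted topic ``j``) and
    the per-topic TV distances.
    """
    est = np.asarray(estimated_phi, dtype=float)
    true = np.asarray(true_phi, dtype=float)
    if est.shape[1] != true.shape[1]:
        raise ValueError("estimated and true topics use different vocabularies")
    if est.shape[0] < true.shape[0]:
        raise ValueError("need at least as many estimated topics as planted ones")
    cost = 0.5 * np.abs(true[:, None, :] - est[None, :, :]).sum(axis=2)  # true x est
    row, col = linear_sum_assignment(cost)
    perm = np.empty(true.shape[0], dtype=np.int64)
    perm[row] = col
    return perm, cost[row, col][np.argsort(row)]
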