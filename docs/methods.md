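# Methods

## From intensities to a token corpus

The input is a genes × samples matrix of positive, pre-normalized
expression intensities and a sample table mapping each sample to drug,
dose level (low/middle/high, or control), time point (3, 7, 14, 28 days)
and replicate. For every treatment (drug, dose, time) the replicate
intensities are averaged per gene (arithmetic mean by default; geometric
available) and divided by the mean of the concurrent control group,
matched on (drug, time); when several control groups match they are
pooled. The ratio r is stored with the reciprocal-signed convention —
`r` if r ≥ 1, `-1/r` otherwise — so the magnitude is max(r, 1/r) and the
1.5 differential-expression cutoff acts symmetrically on induction and
repression. The cutoff is strict (|FC| = 1.5 is *not* a DEG) and zeroed
entries mean "not differentially expressed".

Token counts are `round(scale × |FC|)` with half-to-even rounding and
`scale = 1` by default, so a 2.3-fold change contributes two tokens of
that gene and a 16-fold change sixteen. The mapping is monotone in effect
size and keeps the vocabulary equal to the gene set; an optional
signed-token mode splits each gene into `__up`/`__dn` vocabulary entries
when the direction of regulation must survive discretization. Treatments
whose filtered row is all zero (no DEGs — common for low doses and short
exposures) are dropped with a logged warning rather than an error.

## The author-topic model and its sampler

Documents (treatments) each have exactly one author. At treatment level
the author *is* the document; regrouping by drug or by dose–time pair
reassigns authorship without touching the counts, so the author-sampling
step of the general author-topic model degenerates and inference is
grouped LDA. The collapsed Gibbs conditional for token i (word w, author
a) is

    p(z_i = k | rest) ∝ (n_ak + α_k) (n_kw + β) / (n_k + V β)

with the token removed from all counts. The implementation keeps
incremental count tables whose correctness is enforced by a recount
oracle (a full tally of z must reproduce them exactly) and is validated
against brute-force enumeration of the collapsed posterior on corpora
small enough to enumerate.

**Hyperparameters.** β is symmetric and fixed (default 0.01). α is a
K-vector learned during sampling by Minka's fixed point on the
author–topic counts, floored at 1e-8, iterated to a 1e-6 relative
tolerance; the schedule is MALLET-like — every 10 sweeps after a 200-sweep
burn-in. α starts symmetric at `alpha0 / K` with `alpha0 = 50` (the
common 50/K heuristic). Learning an asymmetric α lets prevalent processes
absorb background usage and is what makes held-out performance insensitive
to overshooting K.

**Point estimates.** By default from the final sample:
θ = (n_ak + α)/(N_a + Σα); smoothed φ = (n_kw + β)/(n_k + Vβ); raw
φ = n_kw/n_k with exact zeros preserved, giving each process a sparse
gene support suitable for export and annotation. Optionally estimates are
averaged over the last S thinned samples (labels are tied by the shared
chain state); averaging reduces single-draw Monte-Carlo noise but blurs
raw-φ zeros into "zero only if never assigned". `restarts > 1` runs
multiple seeded chains and keeps the one with the highest final collapsed
joint log-likelihood — on some corpora a substantial fraction of chains
settles in visibly inferior modes (lower joint likelihood, merged or
split topics), and the likelihood reliably identifies them.

**Convergence.** The collapsed joint log p(w, z) is recorded per sweep;
chains are judged stable when the trailing segment of the trace shows no
trend beyond its noise. All randomness flows from one seed through
`numpy` generators; fixed seeds give bit-identical models.

## Held-out perplexity and choosing K

Perplexity is exp(−mean per-token log Σ_k θ_dk φ_kw) with φ frozen at the
smoothed estimate. Two protocols are implemented:

- **fold_in** (default of `held_out_perplexity`): θ for each held-out
  document is inferred by Gibbs over *all* its tokens, then those same
  tokens are scored. Simple, but biased toward larger K, because θ adapts
  to the tokens being evaluated.
- **completion** (used by `select_num_topics`): θ is inferred from a
  seeded half of each document's tokens and only the other half is
  scored.

The bias of fold-in is not cosmetic: on corpora planted with K = 5, 10-fold
cross-validation under fold-in prefers K = 20 from {2, 5, 20} essentially
always, while document completion recovers the planted K in 9 of 10
repetitions. Model selection therefore uses completion; the argmin of the
mean CV perplexity is recommended, ties broken toward smaller K. On the
full-scale study this package emulates, the published configuration is
K = 200 for the treatment-level model and K = 100 for the drug and
dose–time models.

## Similarity and annotation

sKL(p, q) = KL(p‖q) + KL(q‖p), in nats, always computed on the smoothed
(strictly positive) θ; it is a symmetric premetric (non-negative, zero iff
equal, no triangle inequality). Reported scores depend on the log base
and on the smoothing, so both are fixed and recorded in run manifests.
Ranked similarity lists are ascending in sKL with lexicographic
tie-breaks; top-topic lists break probability ties toward the smaller
process index, top-gene lists toward the lexicographically smaller gene.

Gene lists (the positive support of raw φ per process) are exported as
one-gene-per-line text files for external annotation services. A local
alternative is provided: hypergeometric over-representation against
user-supplied GMT gene sets with Benjamini–Hochberg FDR, the universe
defaulting to the corpus vocabulary size. These p-values are a standard
over-representation test, not a reimplementation of any web service's
modified score.

## Dose/time reducibility

For a drug with the full 12-treatment design, the 66 unordered treatment
pairs give observations (sKL, dose pair, |Δt|). The dose-pair factor has
six levels (Low-Low, Low-Middle, Low-High, Middle-Middle, Middle-High,
High-High). Three variants are fitted by ordinary least squares
(Gaussian-identity — consistent with reporting adjusted R²; a Gamma-log
option with deviance pseudo-R² exists for the strictly positive
response): dose + time, dose only, time only. Dose-containing variants
use full dummy coding with no separate intercept (the factor spans it);
time-only gets an explicit intercept so sKL(Δt = 0) need not vanish.
Adjusted R² is 1 − (1 − R²)(n − 1)/(n − p − 1) with p the number of free
coefficients beyond the intercept; AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ
with k the parameter count. The verdict is "time reducible" only when a
time-free variant wins under *all three* criteria (with the symmetric
"dose reducible" case for completeness); ties prefer the smaller model.

A caveat this package's own simulations make explicit: when the planted
truth is genuinely time-flat, the time coefficient of the dose + time
variant is pure noise, and the adjusted-R² comparison between dose-only
and dose + time reduces to whether that coefficient's t² < 1 — an event
with probability only ≈ 0.7–0.8 per run, which is an upper bound on how
often the unanimous-verdict rule can call a time-flat drug reducible no
matter how strong the dose signal is. End-to-end, dose-driven/time-flat
drugs are called time-reducible in ≈ 80% of seeded runs, while
time-driven drugs are essentially never called time-reducible. A verdict
rule based on BIC alone would be far more sensitive, but the unanimity
rule is kept because it mirrors the conservative "consistent superiority
under all three criteria" logic of the analysis this package
operationalizes.

## Synthetic data

Two generators supply ground truth. `simulate_att_corpus` samples the
generative model itself (topics from Dir(β), author weights from Dir(α),
ancestral tokens). `simulate_tg_study` emulates the factorial study:
per-gene log-normal baselines (log2 mean 8, sd 1), planted co-regulated
modules whose log2 fold change is `amplitude × dose_weight × time_weight`
(so dose/time act multiplicatively on the log scale and penetration of
the 1.5 cutoff is predictable), three replicates per group, and
multiplicative log-normal replicate noise with σ = 0.15 (natural log) — a
realistic combined biological/technical variation for expression arrays.
At these defaults fewer than 5% of non-module gene–treatment entries leak
through the DEG filter. The generator reproduces the statistical
structure the analysis assumes — factorial design, concurrent controls,
module-driven fold changes, sparsity — but none of the physics of real
microarrays (probe affinity, saturation, background correction), so
passing tests demonstrate correctness of the inference machinery, not
robustness to real-data artifacts.

Label switching in recovery experiments is resolved by the Hungarian
algorithm on the total-variation cost matrix (exactly optimal for any K;
surplus estimated topics stay unmatched).

## Problem sizes used in tests

The test suite and acceptance script run at desk scale, chosen so the
whole suite finishes in minutes on one CPU: recovery and model-selection
corpora of 100 documents × 50 tokens over 200 genes; reducibility studies
of 2 drugs × 12 treatments × 3 replicates over 300 genes; sampler
exactness on a 4-token corpus where the collapsed posterior can be
enumerated. Chains run 300–2000 sweeps at these sizes (the trace
stabilizes within a few hundred), versus the 3000 sweeps recommended for
full-scale corpora.

## Known limitations

- At the recovery experiment's scale (≈ 1000 tokens per planted process,
  sparse Dir(0.05) topics), the oracle floor — tallying tokens by their
  true labels — is already a mean total-variation distance of ≈ 0.06–0.08
  from the planted topics, and the exact posterior mean sits at ≈ 0.12;
  an independent variational implementation does worse (≈ 0.18–0.24).
  Recovery below TV 0.10 at these sizes is not achievable by correct
  inference, only by more data.
- Multi-author documents, asymmetric β, and variational or online
  inference are out of scope; one author per document is exact for this
  design, where every treatment belongs to one drug and one dose–time
  pair.
- The unanimous three-criterion reducibility verdict is conservative by
  construction (see above); treat a "not reducible" verdict for a drug
  with an obviously flat axis as a prompt to inspect the per-criterion
  table, which is always emitted alongside the verdict.
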