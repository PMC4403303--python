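import numpy as np
import pytest

from toxitopic import att
from toxitopic.att import (
    ATTModel,
    HyperParams,
    estimate_phi,
    estimate_theta,
    gibbs_sweep,
    held_out_perplexity,
    initialize_state,
    minka_fixed_point,
    optimize_alpha,
    select_num_topics,
    train,
)
from toxitopic.synthetic import simulate_att_corpus

from .conftest import corpus_from_dense


@pytest.fixture(scope="module")
def sim_corpus():
    corpus, _ = simulate_att_corpus(
        K=3, V=40, n_authors=20, docs_per_author=1, tokens_per_doc=30,
        alpha=np.array([1.0, 0.7, 0.4]), beta=0.1, seed=9,
    )
    return corpus


class TestInitializeState:
    def test_k1_assigns_everything_to_topic_zero(self, sim_corpus):
        state = initialize_state(sim_corpus, K=1, seed=4)
        assert (state.z == 0).all()

    def test_same_seed_same_state(self, sim_corpus):
        a = initialize_state(sim_corpus, K=4, seed=11)
        b = initialize_state(sim_corpus, K=4, seed=11)
        assert np.array_equal(a.z, b.z) and np.array_equal(a.n_kw, b.n_kw)

    def test_recount_matches_tables(self, sim_corpus):
        state = initialize_state(sim_corpus, K=4, seed=2)
        state.check_consistent()

    def test_invalid_k_rejected(self):
        corpus = corpus_from_dense([[1]])
        with pytest.raises(ValueError):
            initialize_state(corpus, K=0)


class TestGibbsSweep:
    def test_k1_leaves_state_unchanged(self, sim_corpus):
        state = initialize_state(sim_corpus, K=1, seed=0)
        before = state.z.copy()
        gibbs_sweep(state)
        assert np.array_equal(state.z, before)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_author_row_sums_conserved(self, sim_corpus, seed):
        state = initialize_state(sim_corpus, K=5, seed=seed)
        before = state.n_ak.sum(axis=1).copy()
        for _ in range(5):
            gibbs_sweep(state)
        assert np.array_equal(state.n_ak.sum(axis=1), before)

    def test_counts_stay_consistent_over_sweeps(self, sim_corpus):
        state = initialize_state(sim_corpus, K=3, seed=7)
        for _ in range(20):
            gibbs_sweep(state)
        state.check_consistent()

    def test_inconsistent_state_detected(self, sim_corpus):
        state = initialize_state(sim_corpus, K=3, seed=7)
        state.n_k[0] += 1
        with pytest.raises(ValueError, match="inconsistent"):
            gibbs_sweep(state, check=True)


class TestOptimizeAlpha:
    def test_symmetric_counts_keep_alpha_symmetric(self):
        corpus = corpus_from_dense(np.ones((4, 6), dtype=int))
        state = initialize_state(corpus, K=3, seed=0)
        state.n_ak = np.full((4, 3), 2)  # identical across topics
        state.hyper.alpha = np.array([0.5, 0.5, 0.5])
        optimize_alpha(state)
        assert np.allclose(state.hyper.alpha, state.hyper.alpha[0])

    def test_floor_clamps_instead_of_zeroing(self):
        counts = np.zeros((50, 3), dtype=int)
        counts[:, 0] = 100  # topic 0 takes everything
        alpha = minka_fixed_point(counts, np.array([1.0, 1.0, 1.0]))
        assert (alpha > 0).all()
        assert alpha[1] == pytest.approx(att.ALPHA_FLOOR)

    def test_all_zero_counts_warn_and_leave_alpha(self):
        corpus = corpus_from_dense([[1, 1], [1, 1]])
        state = initialize_state(corpus, K=2, seed=0)
        state.n_ak = np.zeros_like(state.n_ak)
        before = state.hyper.alpha.copy()
        with pytest.warns(UserWarning, match="all-zero"):
            optimize_alpha(state)
        assert np.array_equal(state.hyper.alpha, before)

    def test_recovers_planted_concentration(self):
        rng = np.random.default_rng(0)
        astar = np.array([4.0, 2.0, 1.0])
        theta = rng.dirichlet(astar, size=300)
        counts = np.array([rng.multinomial(150, t) for t in theta])
        est = minka_fixed_point(counts, np.ones(3))
        assert np.max(np.abs(est - astar) / astar) < 0.15


class TestEstimators:
    def test_theta_rows_sum_to_one(self, sim_corpus):
        state = initialize_state(sim_corpus, K=4, seed=3)
        gibbs_sweep(state)
        assert np.allclose(estimate_theta(state).sum(axis=1), 1.0, atol=1e-9)

    def test_zero_token_author_gets_prior_mean(self):
        corpus = corpus_from_dense(
            [[2, 1], [1, 1]], feature_level="drug",
            doc_author=[0, 0], author_ids=["a"],
        )
        state = initialize_state(corpus, K=2, seed=0)
        state.n_ak = np.vstack([state.n_ak.sum(axis=0), [0, 0]])  # add empty author
        state.hyper.alpha = np.array([0.3, 0.7])
        with pytest.warns(UserWarning, match="zero tokens"):
            theta = estimate_theta(state)
        assert np.allclose(theta[1], [0.3, 0.7])

    def test_raw_phi_has_exact_zeros_and_smoothed_does_not(self, sim_corpus):
        state = initialize_state(sim_corpus, K=6, seed=1)
        for _ in range(10):
            gibbs_sweep(state)
        raw = estimate_phi(state, smoothed=False)
        smoothed = estimate_phi(state, smoothed=True)
        assert (raw == 0).any()  # sparse support
        assert (smoothed > 0).all()
        assert np.allclose(smoothed.sum(axis=1), 1.0, atol=1e-9)

    def test_point_mass_topic(self):
        corpus = corpus_from_dense([[1, 0]])
        state = initialize_state(corpus, K=1, seed=0)
        raw = estimate_phi(state, smoothed=False)
        assert raw[0, 0] == 1.0 and raw[0, 1] == 0.0

    def test_empty_topic_flagged_in_raw_mode(self):
        corpus = corpus_from_dense([[3, 1]])
        state = initialize_state(corpus, K=2, seed=0)
        state.z[:] = 0
        state.n_ak, state.n_kw, state.n_k = state.recount()
        with pytest.warns(UserWarning, match="empty topic"):
            raw = estimate_phi(state, smoothed=False)
        assert (raw[1] == 0).all()


class TestTrain:
    def test_fixed_seed_reproduces_estimates_bitwise(self, sim_corpus):
        kwargs = dict(K=3, iterations=30, burn_in=10, loglik_every=0, seed=5)
        m1 = train(sim_corpus, **kwargs)
        m2 = train(sim_corpus, **kwargs)
        assert np.array_equal(m1.theta, m2.theta)
        assert np.array_equal(m1.phi_smoothed, m2.phi_smoothed)
        assert np.array_equal(m1.hyper.alpha, m2.hyper.alpha)

    def test_disjoint_vocabulary_halves_recovered(self):
        # docs 0-4 use genes 0-9, docs 5-9 use genes 10-19
        rng = np.random.default_rng(0)
        counts = np.zeros((10, 20), dtype=int)
        counts[:5, :10] = rng.integers(1, 5, (5, 10))
        counts[5:, 10:] = rng.integers(1, 5, (5, 10))
        corpus = corpus_from_dense(counts)
        model = train(corpus, K=2, iterations=200, burn_in=50, loglik_every=0, seed=1)
        supports = [np.nonzero(row)[0] for row in model.phi_raw]
        halves = {frozenset(s // 10 for s in sup) for sup in supports}
        assert halves == {frozenset({0}), frozenset({1})}

    def test_loglik_trace_stationary_at_end(self, sim_corpus):
        model = train(sim_corpus, K=3, iterations=400, burn_in=100, seed=3)
        tail = model.loglik[-40:]
        drift = abs(np.polyfit(np.arange(len(tail)), tail, 1)[0]) * (len(tail) - 1)
        assert drift < 3 * tail.std(ddof=1)

    def test_sample_averaging_keeps_rows_normalized(self, sim_corpus):
        model = train(
            sim_corpus, K=3, iterations=100, burn_in=20, loglik_every=0,
            seed=2, average_samples=5, sample_thin=10,
        )
        model.validate()

    def test_model_round_trip(self, tmp_path, sim_corpus):
        model = train(sim_corpus, K=3, iterations=20, burn_in=5, seed=8)
        model.save(tmp_path / "m")
        back = ATTModel.load(tmp_path / "m")
        assert np.allclose(back.theta, model.theta)
        assert np.allclose(back.phi_smoothed, model.phi_smoothed)
        assert np.allclose(back.phi_raw, model.phi_raw)
        assert np.allclose(back.hyper.alpha, model.hyper.alpha)
        assert back.author_ids == model.author_ids


class TestPerplexity:
    def _uniform_model(self, K, V):
        return ATTModel(
            theta=np.full((2, K), 1.0 / K),
            phi_smoothed=np.full((K, V), 1.0 / V),
            phi_raw=np.full((K, V), 1.0 / V),
            hyper=HyperParams(np.full(K, 0.5), 0.01, K),
            author_ids=["a", "b"],
            vocabulary=[f"g{j}" for j in range(V)],
            feature_level="treatment",
        )

    def test_uniform_phi_gives_perplexity_v(self):
        V = 11
        heldout = corpus_from_dense([[2, 0, 1] + [0] * (V - 3), [1] * V])
        perp = held_out_perplexity(self._uniform_model(3, V), heldout, seed=0)
        assert perp == pytest.approx(V, rel=1e-12)

    def test_certain_model_gives_perplexity_one(self):
        model = ATTModel(
            theta=np.array([[1.0]]),
            phi_smoothed=np.array([[1.0]]),
            phi_raw=np.array([[1.0]]),
            hyper=HyperParams(np.array([1.0]), 0.01, 1),
            author_ids=["a"],
            vocabulary=["g0"],
            feature_level="treatment",
        )
        heldout = corpus_from_dense([[4]])
        assert held_out_perplexity(model, heldout, seed=0) == pytest.approx(1.0)

    def test_identical_topic_rows_match_direct_formula(self):
        # phi rows equal => sum_k theta_k phi_kw is phi_w whatever theta is
        phi_row = np.array([0.5, 0.3, 0.2])
        model = ATTModel(
            theta=np.array([[0.6, 0.4]]),
            phi_smoothed=np.vstack([phi_row, phi_row]),
            phi_raw=np.vstack([phi_row, phi_row]),
            hyper=HyperParams(np.array([0.4, 0.6]), 0.01, 2),
            author_ids=["a"],
            vocabulary=["g0", "g1", "g2"],
            feature_level="treatment",
        )
        heldout = corpus_from_dense([[2, 1, 0]])
        expected = np.exp(-(2 * np.log(0.5) + np.log(0.3)) / 3)
        assert held_out_perplexity(model, heldout, seed=1) == pytest.approx(expected)

    def test_oov_tokens_dropped_with_warning(self, sim_corpus):
        model = train(sim_corpus, K=2, iterations=20, burn_in=5, loglik_every=0, seed=0)
        heldout = corpus_from_dense([[1, 2]])
        heldout.vocabulary = [sim_corpus.vocabulary[0], "NOT_IN_TRAINING"]
        with pytest.warns(UserWarning, match="out-of-vocabulary"):
            held_out_perplexity(model, heldout, seed=0)

    def test_empty_heldout_rejected(self, sim_corpus):
        model = train(sim_corpus, K=2, iterations=10, burn_in=2, loglik_every=0, seed=0)
        with pytest.raises(ValueError):
            held_out_perplexity(model, corpus_from_dense(np.empty((0, 0))), seed=0)


class TestSelectNumTopics:
    def test_leave_one_out_partition_runs(self):
        corpus, _ = simulate_att_corpus(
            K=2, V=20, n_authors=6, docs_per_author=1, tokens_per_doc=15,
            alpha=np.array([1.0, 1.0]), beta=0.2, seed=0,
        )
        sel = select_num_topics(
            corpus, [2], folds=corpus.n_docs,
            train_kwargs=dict(iterations=20, burn_in=5, loglik_every=0), seed=0,
        )
        assert sel.table.shape == (1, 3)

    def test_empty_grid_rejected(self, sim_corpus):
        with pytest.raises(ValueError):
            select_num_topics(sim_corpus, [], folds=5)

    def test_more_folds_than_documents_rejected(self, sim_corpus):
        with pytest.raises(ValueError):
            select_num_topics(sim_corpus, [2], folds=sim_corpus.n_docs + 1)
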