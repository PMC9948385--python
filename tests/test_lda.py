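"""Collapsed Gibbs sampler: conditionals, sweeps, estimation, likelihood."""

import numpy as np
import pytest

from doublecluster import (
    GibbsState,
    LDAHyperparams,
    conditional_topic_probs,
    counts_to_tokens,
    fit_lda,
    gibbs_sweep,
    log_likelihood,
    sample_corpus,
)

from conftest import chain_rule_joint_logp, make_counts


class TestCountsToTokens:
    def test_definition_and_order(self):
        tokens = counts_to_tokens(make_counts([[2, 0, 1]]))
        np.testing.assert_array_equal(tokens[0], [0, 0, 2])

    def test_empty_document_allowed(self):
        tokens = counts_to_tokens(make_counts([[0, 0, 0], [1, 0, 0]]))
        assert tokens[0].size == 0 and tokens[1].size == 1

    def test_token_total_equals_grand_total(self, tiny_counts):
        tokens = counts_to_tokens(tiny_counts)
        assert sum(t.size for t in tokens) == tiny_counts.counts.sum()


def _hand_state():
    # -i counts: Cwk=[[1,0],[0,1]], topic_totals=(1,1), doc 0 has Cdk=(1,1)
    state = GibbsState(
        token_words=np.array([0, 1, 0], dtype=np.int64),
        token_docs=np.zeros(3, dtype=np.int64),
        z=np.array([0, 1, 0], dtype=np.int64),
        Cwk=np.array([[1, 0], [0, 1]], dtype=np.int64),
        Cdk=np.array([[1, 1]], dtype=np.int64),
        topic_totals=np.array([1, 1], dtype=np.int64),
        doc_totals=np.array([2], dtype=np.int64),
    )
    return state


class TestConditionalTopicProbs:
    def test_hand_evaluated_counts(self):
        hp = LDAHyperparams(K=2, alpha=1.0, beta=1.0, n_iterations=2, n_burnin=0)
        p = conditional_topic_probs(_hand_state(), d=0, w=0, hp=hp)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_single_topic_returns_one(self):
        counts = make_counts([[2, 1]])
        hp = LDAHyperparams(K=1, n_iterations=2, n_burnin=0)
        rng = np.random.default_rng(0)
        state = GibbsState.from_tokens(
            counts_to_tokens(counts), np.zeros(3, int), 2, 1
        )
        state.Cwk[0, 0] -= 1
        state.topic_totals[0] -= 1
        state.Cdk[0, 0] -= 1
        np.testing.assert_allclose(
            conditional_topic_probs(state, 0, 0, hp), [1.0], atol=1e-15
        )

    def test_prior_dominated_limit_is_uniform(self):
        hp = LDAHyperparams(K=2, alpha=1e9, beta=1e9, n_iterations=2, n_burnin=0)
        p = conditional_topic_probs(_hand_state(), d=0, w=0, hp=hp)
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-6)

    def test_negative_minus_i_count_raises(self):
        state = _hand_state()
        state.Cwk[0, 0] = -1
        hp = LDAHyperparams(K=2, n_iterations=2, n_burnin=0)
        with pytest.raises(ValueError, match="bookkeeping"):
            conditional_topic_probs(state, 0, 0, hp)


class TestGibbsSweep:
    def _state(self, counts, hp, seed=0):
        tokens = counts_to_tokens(counts)
        total = counts.counts.sum()
        rng = np.random.default_rng(seed)
        z = rng.integers(0, hp.K, total)
        return GibbsState.from_tokens(tokens, z, counts.W, hp.K), rng

    def test_counts_match_recount_after_sweeps(self, tiny_counts):
        hp = LDAHyperparams(K=3, n_iterations=5, n_burnin=0)
        state, rng = self._state(tiny_counts, hp)
        for _ in range(5):
            gibbs_sweep(state, hp, rng)
            Cwk, Cdk = state.recount()
            np.testing.assert_array_equal(Cwk, state.Cwk)
            np.testing.assert_array_equal(Cdk, state.Cdk)
            np.testing.assert_array_equal(Cwk.sum(0), state.topic_totals)
            np.testing.assert_array_equal(Cdk.sum(1), state.doc_totals)

    def test_single_topic_leaves_counts_invariant(self, tiny_counts):
        hp = LDAHyperparams(K=1, n_iterations=2, n_burnin=0)
        state, rng = self._state(tiny_counts, hp)
        before = state.Cwk.copy()
        gibbs_sweep(state, hp, rng)
        np.testing.assert_array_equal(state.Cwk, before)
        assert np.all(state.z == 0)

    def test_sweep_is_reproducible(self, tiny_counts):
        hp = LDAHyperparams(K=2, n_iterations=2, n_burnin=0)
        s1, r1 = self._state(tiny_counts, hp, seed=4)
        s2, r2 = self._state(tiny_counts, hp, seed=4)
        gibbs_sweep(s1, hp, r1)
        gibbs_sweep(s2, hp, r2)
        np.testing.assert_array_equal(s1.z, s2.z)


class TestFitLDA:
    def test_disjoint_vocabularies_concentrate(self):
        counts = make_counts([[6, 0], [0, 6]])
        hp = LDAHyperparams(
            K=2, alpha=0.1, beta=0.1, n_iterations=400, n_burnin=100, seed=1
        )
        model, _ = fit_lda(counts, hp)
        top = model.theta.argmax(axis=1)
        assert top[0] != top[1]
        assert model.theta[0, top[0]] > 0.9 and model.theta[1, top[1]] > 0.9
        assert model.phi[top[0], 0] > 0.9 and model.phi[top[1], 1] > 0.9

    def test_single_topic_closed_form(self, tiny_counts):
        hp = LDAHyperparams(K=1, beta=0.1, n_iterations=10, n_burnin=2, seed=0)
        model, state = fit_lda(tiny_counts, hp)
        np.testing.assert_array_equal(model.theta, 1.0)
        T = tiny_counts.counts.sum()
        n_w = tiny_counts.counts.sum(axis=0)
        expected = (n_w + hp.beta) / (T + tiny_counts.W * hp.beta)
        np.testing.assert_allclose(model.phi[0], expected, atol=1e-12)

    def test_rows_stochastic_and_positive(self, tiny_counts):
        hp = LDAHyperparams(K=3, n_iterations=20, n_burnin=5, seed=0)
        model, _ = fit_lda(tiny_counts, hp)
        np.testing.assert_allclose(model.theta.sum(1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.phi.sum(1), 1.0, atol=1e-9)
        assert np.all(model.theta > 0) and np.all(model.phi > 0)

    def test_all_empty_corpus_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fit_lda(
                make_counts([[0, 0], [0, 0]]),
                LDAHyperparams(K=2, n_iterations=5, n_burnin=0),
            )

    def test_deterministic_given_seed(self, tiny_counts):
        hp = LDAHyperparams(K=2, n_iterations=30, n_burnin=10, seed=9)
        m1, s1 = fit_lda(tiny_counts, hp)
        m2, s2 = fit_lda(tiny_counts, hp)
        np.testing.assert_array_equal(m1.theta, m2.theta)
        np.testing.assert_array_equal(s1.z, s2.z)

    def test_parameter_recovery_modest_scale(self):
        rng = np.random.default_rng(7)
        phi = np.array(
            [[0.35, 0.25, 0.15, 0.1, 0.05, 0.1], [0.05, 0.1, 0.1, 0.15, 0.3, 0.3]]
        )
        theta = rng.dirichlet([0.3, 0.3], size=60)
        counts = sample_corpus(theta, phi, np.full(60, 150), rng)
        hp = LDAHyperparams(K=2, n_iterations=300, n_burnin=100, seed=3)
        model, _ = fit_lda(counts, hp)
        tv_direct = 0.5 * np.abs(model.phi - phi).sum(axis=1)
        tv_swapped = 0.5 * np.abs(model.phi[::-1] - phi).sum(axis=1)
        assert min(tv_direct.max(), tv_swapped.max()) < 0.1


class TestLogLikelihood:
    def test_empty_corpus_is_zero(self):
        state = GibbsState.from_tokens(
            [np.empty(0, np.int64)], np.empty(0, np.int64), W=3, K=2
        )
        hp = LDAHyperparams(K=2, n_iterations=2, n_burnin=0)
        assert log_likelihood(state, hp) == 0.0

    def test_single_token_single_topic_single_word(self):
        state = GibbsState.from_tokens(
            [np.array([0])], np.array([0]), W=1, K=1
        )
        hp = LDAHyperparams(K=1, beta=0.7, n_iterations=2, n_burnin=0)
        assert abs(log_likelihood(state, hp)) < 1e-12

    def test_matches_chain_rule_oracle(self):
        words = np.array([0, 1, 0, 2, 1], dtype=np.int64)
        docs = np.array([0, 0, 0, 1, 1], dtype=np.int64)
        z = np.array([0, 1, 0, 1, 0], dtype=np.int64)
        state = GibbsState.from_tokens(
            [words[docs == 0], words[docs == 1]], z, W=3, K=2
        )
        hp = LDAHyperparams(K=2, alpha=0.7, beta=0.4, n_iterations=2, n_burnin=0)
        oracle = chain_rule_joint_logp(words, docs, z, 3, 2, hp.alpha, hp.beta)
        assert abs(log_likelihood(state, hp) - oracle) < 1e-10

    def test_invariant_under_topic_relabeling(self):
        words = np.array([0, 1, 0, 2, 1, 2], dtype=np.int64)
        docs = np.array([0, 0, 0, 1, 1, 1], dtype=np.int64)
        z = np.array([0, 1, 0, 1, 0, 1], dtype=np.int64)
        hp = LDAHyperparams(K=2, n_iterations=2, n_burnin=0)
        tokens = [words[docs == 0], words[docs == 1]]
        s = GibbsState.from_tokens(tokens, z, W=3, K=2)
        s_flip = GibbsState.from_tokens(tokens, 1 - z, W=3, K=2)
        assert abs(log_likelihood(s, hp) - log_likelihood(s_flip, hp)) < 1e-12
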