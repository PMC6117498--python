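"""Gibbs sampler correctness: conditional distributions against a brute-force
collapsed-posterior oracle, count conservation, labeled/unlabeled equivalence,
estimation arithmetic, fold-in, perplexity and topic-number selection."""

import numpy as np
import pytest
from scipy.special import gammaln

import reviewminer as rm
from reviewminer.topic_model import LdaState, TopicModelResult


# ---------------------------------------------------------------------------
# Oracle: collapsed joint probability p(w, z) for tiny instances
# ---------------------------------------------------------------------------

def collapsed_log_joint(bows, z_by_doc, K, V, alpha, beta):
    """log p(w, z) with theta and phi integrated out (Polya identities)."""
    M = len(bows)
    n_dk = np.zeros((M, K))
    n_kw = np.zeros((K, V))
    for d, (bow, zs) in enumerate(zip(bows, z_by_doc)):
        for w, k in zip(bow, zs):
            n_dk[d, k] += 1
            n_kw[k, w] += 1
    ll = 0.0
    for d in range(M):
        ll += gammaln(K * alpha) - gammaln(n_dk[d].sum() + K * alpha)
        ll += (gammaln(n_dk[d] + alpha) - gammaln(alpha)).sum()
    for k in range(K):
        ll += gammaln(V * beta) - gammaln(n_kw[k].sum() + V * beta)
        ll += (gammaln(n_kw[k] + beta) - gammaln(beta)).sum()
    return ll


def test_one_step_conditional_matches_collapsed_posterior_oracle():
    """On a 3-document, 2-topic, 5-word instance the sampler's one-step
    conditional equals brute-force evaluation of p(z_t=k | z_-t, w)."""
    bows = [[0, 1, 2], [2, 3, 4, 0], [1, 1, 3]]
    K, V, alpha, beta = 2, 5, 0.7, 0.3
    state = rm.fit_lda(bows, V, K=K, alpha=alpha, beta=beta,
                       iterations=3, burn_in=3, seed=42)
    z_by_doc = []
    pos = 0
    for bow in bows:
        z_by_doc.append(list(state.z[pos:pos + len(bow)]))
        pos += len(bow)
    t = 0
    for d, bow in enumerate(bows):
        for i in range(len(bow)):
            direct = rm.gibbs_conditional(state, t)
            logp = []
            for k in range(K):
                trial = [list(zs) for zs in z_by_doc]
                trial[d][i] = k
                logp.append(collapsed_log_joint(bows, trial, K, V, alpha, beta))
            logp = np.array(logp)
            oracle = np.exp(logp - logp.max())
            oracle /= oracle.sum()
            np.testing.assert_allclose(direct, oracle, atol=1e-12)
            t += 1


# ---------------------------------------------------------------------------
# Count conservation and labeled/unlabeled equivalence
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_corpus_bows():
    config = rm.GeneratorConfig(
        L=9, vocab_size=60, group_sizes={"g": 40},
        label_prevalence={"g": [0.4] * 9},
        default_doc_length=(25.0, None), seed=2)
    corpus, _ = rm.generate_corpus(config)
    vocab = rm.build_vocabulary(corpus)
    return corpus, vocab, rm.docs_to_bow(corpus, vocab)


def test_count_conservation_after_sweeps(tiny_corpus_bows):
    corpus, vocab, bows = tiny_corpus_bows
    state = rm.fit_lda(bows, vocab.V, K=4, iterations=7, burn_in=3,
                       sample_lag=2, seed=0)
    state.check_counts()
    assert (state.n_dk.sum(axis=1) == np.array([len(b) for b in bows])).all()
    assert (state.n_kw.sum(axis=1) == state.n_k).all()


def test_full_label_sets_reduce_to_plain_lda(tiny_corpus_bows, taxonomy):
    """Labeled-LDA with every label on every document is bit-identical to
    unsupervised LDA under a shared seed."""
    corpus, vocab, bows = tiny_corpus_bows
    full = [set(taxonomy.label_ids)] * len(bows)
    a = rm.fit_lda(bows, vocab.V, K=9, iterations=20, burn_in=10, seed=123)
    b = rm.fit_labeled_lda(bows, vocab.V, full, taxonomy,
                           iterations=20, burn_in=10, seed=123)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.n_kw, b.n_kw)


def test_labeled_lda_respects_label_sets(tiny_corpus_bows, taxonomy):
    corpus, vocab, bows = tiny_corpus_bows
    labels = [r.labels for r in corpus]
    state = rm.fit_labeled_lda(bows, vocab.V, labels, taxonomy,
                               iterations=10, burn_in=5, seed=1)
    state.check_counts()   # includes the z-in-label-set check


def test_single_label_documents_get_point_mass_theta(taxonomy):
    config = rm.GeneratorConfig(
        L=9, vocab_size=60, group_sizes={"g": 30},
        label_prevalence={"g": [0.4] * 9}, labels_per_doc={1: 1.0},
        default_doc_length=(20.0, None), seed=6)
    corpus, _ = rm.generate_corpus(config)
    vocab = rm.build_vocabulary(corpus)
    bows = rm.docs_to_bow(corpus, vocab)
    state = rm.fit_labeled_lda(bows, vocab.V, [r.labels for r in corpus],
                               taxonomy, iterations=10, burn_in=5, seed=1)
    theta = rm.estimate_theta_phi(state).theta
    for d, r in enumerate(corpus):
        k = taxonomy.index(next(iter(r.labels)))
        assert theta[d].argmax() == k   # all sampled mass on the single label


def test_empty_label_set_rejected(taxonomy):
    with pytest.raises(ValueError, match="empty label set"):
        rm.fit_labeled_lda([[0, 1]], 5, [set()], taxonomy, iterations=2,
                           burn_in=1, seed=0)


def test_k_below_two_and_empty_corpus_rejected():
    with pytest.raises(ValueError):
        rm.fit_lda([[0]], 5, K=1, iterations=1, burn_in=1, seed=0)
    with pytest.raises(ValueError):
        rm.fit_lda([], 5, K=2, iterations=1, burn_in=1, seed=0)


# ---------------------------------------------------------------------------
# Estimation arithmetic
# ---------------------------------------------------------------------------

def _manual_state(n_dk, n_kw, alpha, beta):
    n_dk = np.asarray(n_dk, dtype=np.int64)
    n_kw = np.asarray(n_kw, dtype=np.int64)
    M, K = n_dk.shape
    V = n_kw.shape[1]
    return LdaState(
        K=K, V=V, alpha=alpha, beta=beta,
        token_doc=np.zeros(0, np.int32), token_word=np.zeros(0, np.int32),
        z=np.zeros(0, np.int32), n_dk=n_dk, n_kw=n_kw,
        n_k=n_kw.sum(axis=1), label_mask=np.ones((M, K)),
        seed=0, iterations=0, burn_in=0, sample_lag=1,
    )


def test_theta_phi_exact_fractions():
    """1 doc, 2 topics, 3 tokens: smoothed count fractions, by hand."""
    state = _manual_state(n_dk=[[2, 1]], n_kw=[[1, 1, 0], [1, 0, 0]],
                          alpha=0.5, beta=0.1)
    res = rm.estimate_theta_phi(state, averaged=False)
    np.testing.assert_allclose(res.theta[0], [2.5 / 4, 1.5 / 4], atol=1e-15)
    np.testing.assert_allclose(res.phi[0], [1.1 / 2.3, 1.1 / 2.3, 0.1 / 2.3],
                               atol=1e-15)
    np.testing.assert_allclose(res.phi[1], [1.1 / 1.3, 0.1 / 1.3, 0.1 / 1.3],
                               atol=1e-15)


def test_empty_document_gets_uniform_prior_row():
    state = _manual_state(n_dk=[[0, 0], [3, 1]], n_kw=[[2, 1, 0], [1, 0, 1]],
                          alpha=0.5, beta=0.1)
    res = rm.estimate_theta_phi(state, averaged=False)
    np.testing.assert_allclose(res.theta[0], [0.5, 0.5])
    np.testing.assert_allclose(res.theta.sum(axis=1), 1.0)
    np.testing.assert_allclose(res.phi.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# Recovery on a single-topic corpus
# ---------------------------------------------------------------------------

def test_single_topic_corpus_collapses_onto_one_column():
    config = rm.GeneratorConfig(
        L=2, vocab_size=30, group_sizes={"g": 60},
        label_prevalence={"g": [1.0, 0.0]},
        default_doc_length=(80.0, None), seed=8)
    corpus, _ = rm.generate_corpus(config)
    vocab = rm.build_vocabulary(corpus)
    bows = rm.docs_to_bow(corpus, vocab)
    # sparse doc-topic prior: the right choice when documents are expected
    # to be (near) single-topic
    state = rm.fit_lda(bows, vocab.V, K=2, alpha=0.01, beta=0.1,
                       iterations=500, burn_in=250, seed=3)
    theta = rm.estimate_theta_phi(state).theta
    dominant = theta.max(axis=1) > 0.8
    assert dominant.mean() >= 0.95


# ---------------------------------------------------------------------------
# Fold-in inference
# ---------------------------------------------------------------------------

def test_fold_in_identifies_generating_topic():
    rng = np.random.default_rng(10)
    V, K = 40, 3
    phi = rng.dirichlet([0.1] * V, size=K)
    phi = np.maximum(phi, 1e-12)
    phi /= phi.sum(axis=1, keepdims=True)
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        k = rep % K
        doc = rng.choice(V, size=200, p=phi[k]).tolist()
        theta = rm.infer_theta([doc], phi, alpha=0.5, seed=rep)
        hits += int(theta[0].argmax() == k)
    assert hits >= 0.95 * n_rep


def test_fold_in_empty_doc_uniform_and_deterministic():
    phi = np.full((4, 10), 0.1)
    with pytest.warns(UserWarning, match="uniform"):
        theta = rm.infer_theta([[]], phi, seed=0)
    np.testing.assert_allclose(theta[0], 0.25)
    docs = [[1, 2, 3, 1], [0, 0, 9]]
    a = rm.infer_theta(docs, phi, seed=5)
    b = rm.infer_theta(docs, phi, seed=5)
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# Perplexity
# ---------------------------------------------------------------------------

def test_uniform_model_perplexity_equals_vocabulary_size():
    V, K, M = 50, 3, 4
    theta = np.full((M, K), 1.0 / K)
    phi = np.full((K, V), 1.0 / V)
    bows = [[0, 1, 2], [5], [7, 7], [V - 1]]
    assert rm.perplexity_from_theta(theta, phi, bows) == pytest.approx(V, abs=1e-9)


def test_certain_model_perplexity_is_one():
    theta = np.array([[1.0 - 1e-15, 1e-15]])
    phi = np.array([[1.0 - 1e-15, 1e-15], [1e-15, 1.0 - 1e-15]])
    ppl = rm.perplexity_from_theta(theta, phi / phi.sum(1, keepdims=True), [[0, 0]])
    assert ppl == pytest.approx(1.0, abs=1e-6)


def test_two_doc_perplexity_hand_computed():
    """Geometric-mean inverse likelihood on a fixed 2-doc toy."""
    theta = np.array([[0.6, 0.4], [0.2, 0.8]])
    phi = np.array([[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]])
    bows = [[0, 2], [1, 2, 2]]
    probs = [0.6 * 0.5 + 0.4 * 0.1,      # doc0 word0
             0.6 * 0.2 + 0.4 * 0.8,      # doc0 word2
             0.2 * 0.3 + 0.8 * 0.1,      # doc1 word1
             0.2 * 0.2 + 0.8 * 0.8,      # doc1 word2 (x2)
             0.2 * 0.2 + 0.8 * 0.8]
    expected = np.exp(-np.log(probs).sum() / 5)
    assert rm.perplexity_from_theta(theta, phi, bows) == pytest.approx(
        expected, abs=1e-12)


def test_perplexity_requires_tokens():
    theta = np.full((1, 2), 0.5)
    phi = np.full((2, 4), 0.25)
    with pytest.raises(ValueError):
        rm.perplexity_from_theta(theta, phi, [[]])


# ---------------------------------------------------------------------------
# Topic-number selection
# ---------------------------------------------------------------------------

def test_select_k_curve_and_degenerate_threshold(tiny_corpus_bows):
    corpus, vocab, bows = tiny_corpus_bows
    curve = rm.select_num_topics(bows, vocab.V, [2, 3, 4],
                                 held_out_fraction=0.25, seed=0,
                                 threshold=0.0, iterations=30, burn_in=15)
    assert [k for k, _ in curve.points] == [2, 3, 4]
    assert all(ppl >= 1.0 for _, ppl in curve.points)
    assert curve.recommended_k == 4     # threshold 0: rule degenerates to max
    with pytest.raises(ValueError):
        rm.select_num_topics(bows, vocab.V, [3], seed=0)


# ---------------------------------------------------------------------------
# Top words
# ---------------------------------------------------------------------------

def test_top_words_ranking_and_ties():
    phi = np.array([[0.05, 0.4, 0.4, 0.15]])
    res = TopicModelResult(np.array([[1.0]]), phi / phi.sum(1, keepdims=True))
    assert rm.top_words(res, 0, 3) == [1, 2, 3]   # tie broken by index
    # one word carries (almost) all the mass
    phi2 = np.array([[1 - 3e-9, 1e-9, 1e-9, 1e-9]])
    res2 = TopicModelResult(np.array([[1.0]]), phi2 / phi2.sum(1, keepdims=True))
    assert rm.top_words(res2, 0, 1) == [0]
    with pytest.raises(ValueError):
        rm.top_words(res, 0, 10)


def test_top_words_matches_sort_oracle():
    rng = np.random.default_rng(0)
    row = rng.dirichlet([0.5] * 25)
    res = TopicModelResult(np.array([[1.0]]), row[None, :] / row.sum())
    got = rm.top_words(res, 0, 25)
    oracle = sorted(range(25), key=lambda i: (-res.phi[0][i], i))
    assert got == oracle
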