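"""HDBSCAN clustering, class-term matrices, c-TF-IDF and topic labelling."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from litmap import (
    Corpus,
    PublicationRecord,
    SyntheticSpec,
    StubLabelBackend,
    TopicRepresentation,
    build_class_term_matrix,
    build_label_prompt,
    cluster_embeddings,
    ctfidf_weights,
    generate_cluster_embeddings,
    generate_corpus,
    label_topics,
    representative_documents,
    top_topic_terms,
    topic_representations,
)
from litmap.topic_model import (
    EXAMPLE_PROMPT,
    MAIN_PROMPT_TEMPLATE,
    SYSTEM_PROMPT,
    ClassTermMatrix,
)


def _corpus(abstracts):
    return Corpus(records=[
        PublicationRecord(
            pmid=str(i), title="T", abstract=text, journal_title="J",
            year=2000, language="eng", authors="A B",
        )
        for i, text in enumerate(abstracts)
    ])


def scalar_ctfidf(tf):
    """Independent scalar implementation of the class-based TF-IDF formula."""
    tf = np.asarray(tf, float)
    n_classes, n_terms = tf.shape
    A = sum(tf[c].sum() for c in range(n_classes)) / n_classes
    W = np.zeros_like(tf)
    for c in range(n_classes):
        for t in range(n_terms):
            f = sum(tf[k, t] for k in range(n_classes))
            if f > 0:
                W[c, t] = tf[c, t] * np.log(1 + A / f)
    return W


class TestClustering:
    def test_small_input_all_outliers_with_warning(self, rng):
        with pytest.warns(UserWarning, match="min_cluster_size"):
            labels = cluster_embeddings(rng.normal(size=(20, 4)))
        assert set(labels.tolist()) == {-1}

    def test_planted_clusters_recovered_exactly(
        self, default_ledger, cluster_embeddings_matrix
    ):
        labels = cluster_embeddings(
            cluster_embeddings_matrix, min_cluster_size=50, min_samples=30
        )
        assert sorted(set(labels.tolist())) == [0, 1, 2]
        assert adjusted_rand_score(default_ledger.topic_ids, labels) == 1.0

    def test_uniform_points_all_outliers(self, rng):
        points = rng.uniform(size=(400, 2))
        labels = cluster_embeddings(
            points, min_cluster_size=100, min_samples=80
        )
        assert set(labels.tolist()) == {-1}

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_stable_across_generator_seeds(self, seed):
        generated = generate_corpus(
            SyntheticSpec(n_topics=3, docs_per_topic=100, seed=seed)
        )
        X = generate_cluster_embeddings(
            generated.ledger, d=128, separation=10.0, seed=seed
        )
        labels = cluster_embeddings(X, min_cluster_size=25, min_samples=15)
        assert adjusted_rand_score(
            generated.ledger.topic_ids, labels
        ) >= 0.95

    def test_membership_partition_is_complete(
        self, cluster_embeddings_matrix
    ):
        labels = cluster_embeddings(
            cluster_embeddings_matrix, min_cluster_size=50, min_samples=30
        )
        assert (labels != -1).sum() + (labels == -1).sum() == len(labels)


class TestClassTermMatrix:
    def test_disjoint_vocabularies_give_block_diagonal(self):
        corpus = _corpus(
            ["apple banana cherry"] * 3 + ["dolphin eagle falcon"] * 3
        )
        assignment = np.array([0, 0, 0, 1, 1, 1])
        matrix = build_class_term_matrix(
            corpus, assignment, min_df=1, ngram_range=(1, 1)
        )
        counts = matrix.counts
        terms = matrix.terms
        for row, vocab in enumerate(
            [{"apple", "banana", "cherry"}, {"dolphin", "eagle", "falcon"}]
        ):
            for j, term in enumerate(terms):
                assert (counts[row, j] > 0) == (term in vocab)

    def test_min_df_threshold_edge(self):
        # "rare" appears in 9 of 12 abstracts: present at min_df=9,
        # absent at min_df=10
        abstracts = [
            "common rare filler" if i < 9 else "common filler extra"
            for i in range(12)
        ]
        corpus = _corpus(abstracts)
        assignment = np.zeros(12, dtype=int)
        kept = build_class_term_matrix(
            corpus, assignment, min_df=9, ngram_range=(1, 1)
        )
        assert "rare" in kept.terms
        pruned = build_class_term_matrix(
            corpus, assignment, min_df=10, ngram_range=(1, 1)
        )
        assert "rare" not in pruned.terms

    def test_outliers_excluded_and_alignment_checked(self):
        corpus = _corpus(["alpha beta"] * 4)
        assignment = np.array([0, 0, -1, -1])
        matrix = build_class_term_matrix(
            corpus, assignment, min_df=1, ngram_range=(1, 1)
        )
        assert matrix.counts[0].sum() == 4  # 2 docs x 2 tokens
        with pytest.raises(ValueError, match="aligned"):
            build_class_term_matrix(corpus, np.zeros(3, dtype=int), min_df=1)
        with pytest.raises(ValueError, match="outlier"):
            build_class_term_matrix(
                corpus, np.full(4, -1), min_df=1
            )

    def test_planted_per_topic_counts(self, default_corpus, default_ledger):
        matrix = build_class_term_matrix(
            default_corpus, default_ledger.topic_ids,
            min_df=5, ngram_range=(1, 1),
        )
        term_index = {term: j for j, term in enumerate(matrix.terms)}
        # every planted topic term count matches generator bookkeeping
        for topic, vocab in enumerate(default_ledger.topic_vocabularies):
            docs = default_ledger.topic_ids == topic
            for term in vocab:
                expected = sum(
                    default_corpus.records[i].abstract.split().count(term)
                    for i in np.flatnonzero(docs)
                )
                assert matrix.counts[topic, term_index[term]] == expected


class TestCtfidf:
    def test_matches_scalar_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            shape = (rng.integers(2, 6), rng.integers(3, 12))
            tf = rng.integers(0, 20, size=shape)
            if tf.sum() == 0:
                tf[0, 0] = 1
            matrix = ClassTermMatrix(
                counts=tf,
                terms=[f"t{j}" for j in range(shape[1])],
                topic_ids=list(range(shape[0])),
                doc_term=None, doc_indices=None, doc_topics=None,
            )
            W = ctfidf_weights(matrix)
            expected = scalar_ctfidf(tf)
            mask = expected != 0
            rel = np.abs(W[mask] - expected[mask]) / np.abs(expected[mask])
            assert rel.max() < 1e-10 if mask.any() else True
            np.testing.assert_array_equal(W[~mask], expected[~mask])

    def test_hand_sized_fixture(self):
        tf = np.array([[4.0, 1.0], [0.0, 1.0]])
        matrix = ClassTermMatrix(
            counts=tf, terms=["a", "b"], topic_ids=[0, 1],
            doc_term=None, doc_indices=None, doc_topics=None,
        )
        W = ctfidf_weights(matrix)
        A = (5 + 1) / 2
        assert W[0, 0] == pytest.approx(4 * np.log(1 + A / 4), rel=1e-12)
        assert W[0, 1] == pytest.approx(1 * np.log(1 + A / 2), rel=1e-12)
        assert W[1, 1] == pytest.approx(1 * np.log(1 + A / 2), rel=1e-12)
        assert W[1, 0] == 0.0

    def test_uniform_term_gets_equal_weights(self):
        tf = np.array([[3.0, 7.0], [3.0, 2.0], [3.0, 1.0]])
        matrix = ClassTermMatrix(
            counts=tf, terms=["same", "other"], topic_ids=[0, 1, 2],
            doc_term=None, doc_indices=None, doc_topics=None,
        )
        W = ctfidf_weights(matrix)
        assert W[0, 0] == W[1, 0] == W[2, 0]

    def test_scaling_counts_preserves_rankings(self, rng):
        tf = rng.integers(0, 15, size=(3, 10)) + 1
        def rankings(counts):
            matrix = ClassTermMatrix(
                counts=counts, terms=[f"t{j}" for j in range(10)],
                topic_ids=[0, 1, 2],
                doc_term=None, doc_indices=None, doc_topics=None,
            )
            W = ctfidf_weights(matrix)
            return [tuple(np.argsort(-row, kind="stable")) for row in W]
        assert rankings(tf) == rankings(tf * 7)

    def test_empty_matrix_rejected(self):
        matrix = ClassTermMatrix(
            counts=np.zeros((2, 3)), terms=["a", "b", "c"], topic_ids=[0, 1],
            doc_term=None, doc_indices=None, doc_topics=None,
        )
        with pytest.raises(ValueError, match="empty"):
            ctfidf_weights(matrix)

    def test_sublinear_variant_damps_frequencies(self):
        tf = np.array([[100.0, 1.0], [1.0, 100.0]])
        matrix = ClassTermMatrix(
            counts=tf, terms=["a", "b"], topic_ids=[0, 1],
            doc_term=None, doc_indices=None, doc_topics=None,
        )
        plain = ctfidf_weights(matrix)
        damped = ctfidf_weights(matrix, sublinear_tf=True)
        assert damped[0, 0] < plain[0, 0]
        assert damped[0, 0] == pytest.approx(
            (1 + np.log(100)) * np.log(1 + 101 / 101), rel=1e-12
        )


class TestRepresentativeDocsAndLabels:
    def _pipeline(self, abstracts, assignment):
        corpus = _corpus(abstracts)
        matrix = build_class_term_matrix(
            corpus, np.asarray(assignment), min_df=1, ngram_range=(1, 1)
        )
        weights = ctfidf_weights(matrix)
        return corpus, matrix, weights

    def test_small_topic_returns_all_members(self):
        corpus, matrix, weights = self._pipeline(
            ["apple banana", "apple cherry", "banana cherry"], [0, 0, 0]
        )
        reps = representative_documents(corpus, matrix, weights)
        assert len(reps[0]) == 3

    def test_doc_of_top_terms_ranks_first(self):
        # doc 0 consists solely of topic 0's discriminative terms; docs 1-2
        # dilute them with vocabulary shared with topic 1 (low idf)
        abstracts = (
            ["plants stress genes"]
            + ["plants shared words here", "stress shared words here"]
            + ["shared words here metal", "shared words here acid",
               "metal acid spectra"]
        )
        corpus, matrix, weights = self._pipeline(
            abstracts, [0, 0, 0, 1, 1, 1]
        )
        reps = representative_documents(corpus, matrix, weights)
        assert reps[0][0] == 0

    def test_cap_is_respected(self):
        abstracts = [f"alpha beta word{i}" for i in range(150)]
        corpus, matrix, weights = self._pipeline(abstracts, [0] * 150)
        reps = representative_documents(
            corpus, matrix, weights, per_topic_cap=100
        )
        assert len(reps[0]) == 100

    def test_prompt_is_deterministic_and_ordered(self):
        topic = TopicRepresentation(
            topic_id=0,
            terms=[("plants", 3.0), ("stress", 2.0), ("genes", 1.0)],
            representative_docs=["doc one", "doc two"],
        )
        prompt_a = build_label_prompt(topic)
        prompt_b = build_label_prompt(topic)
        assert prompt_a == prompt_b
        assert prompt_a.index(SYSTEM_PROMPT) < prompt_a.index("Example:")
        assert prompt_a.index("Example:") < prompt_a.index(
            "Now label this topic."
        )
        assert "plants, stress, genes" in prompt_a
        assert "- doc one" in prompt_a

    def test_stub_backend_joins_top3_terms(self):
        topic = TopicRepresentation(
            topic_id=0,
            terms=[("plants", 3.0), ("stress", 2.0), ("genes", 1.0),
                   ("leaves", 0.5)],
            representative_docs=["d"],
        )
        labels = label_topics([topic], StubLabelBackend())
        assert labels[0] == "plants / stress / genes"
        assert topic.label == "plants / stress / genes"

    def test_backend_failure_falls_back_to_topic_id(self):
        class Exploding:
            def generate(self, prompt, topic):
                raise RuntimeError("api down")

        topic = TopicRepresentation(
            topic_id=7, terms=[("a", 1.0)], representative_docs=["d"]
        )
        labels = label_topics([topic], Exploding())
        assert labels[7] == "Topic 7"

    def test_end_to_end_representations(
        self, default_corpus, default_ledger
    ):
        matrix = build_class_term_matrix(
            default_corpus, default_ledger.topic_ids, min_df=5
        )
        weights = ctfidf_weights(matrix)
        reps = topic_representations(default_corpus, matrix, weights)
        assert [r.topic_id for r in reps] == [0, 1, 2]
        labels = label_topics(reps)
        for rep in reps:
            vocab = set(default_ledger.topic_vocabularies[rep.topic_id])
            assert all(term in vocab for term, _ in rep.terms)
            assert labels[rep.topic_id] == " / ".join(
                term for term, _ in rep.terms[:3]
            )
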