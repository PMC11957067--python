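"""Density-based topic modelling with c-TF-IDF and offline labelling.

Clusters planted-cluster embeddings with HDBSCAN, scores per-topic terms
with class-based TF-IDF, picks representative abstracts, and labels each
topic with the offline stub backend (top-3 terms); the assembled three-part
prompt is what a text-generation backend would receive.
"""

from litmap import (
    SyntheticSpec,
    build_class_term_matrix,
    build_label_prompt,
    cluster_embeddings,
    ctfidf_weights,
    generate_cluster_embeddings,
    generate_corpus,
    label_topics,
    topic_representations,
)

generated = generate_corpus(
    SyntheticSpec(n_topics=3, docs_per_topic=200, seed=0)
)
corpus = generated.corpus
X = generate_cluster_embeddings(generated.ledger, d=768, seed=0)

# full-scale defaults are 500/300; scaled to this 600-document corpus
assignment = cluster_embeddings(X, min_cluster_size=50, min_samples=30)
n_topics = len(set(assignment.tolist()) - {-1})
n_outliers = int((assignment == -1).sum())
print(f"{n_topics} topics found, {n_outliers} outlier documents")

matrix = build_class_term_matrix(corpus, assignment, min_df=5)
weights = ctfidf_weights(matrix)
topics = topic_representations(corpus, matrix, weights, n_terms=10)
labels = label_topics(topics)  # offline stub: top-3 terms joined

for topic in topics:
    terms = ", ".join(term for term, _ in topic.terms[:5])
    print(f"\ntopic {topic.topic_id} -> label: {labels[topic.topic_id]}")
    print(f"  top c-TF-IDF terms: {terms}")
    print(f"  representative abstracts: {len(topic.representative_docs)}")

prompt = build_label_prompt(topics[0])
print(f"\nprompt for topic 0 is {len(prompt)} characters; first lines:")
print("\n".join(prompt.splitlines()[:2]))
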