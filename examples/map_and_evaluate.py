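"""Project embeddings to a 2-D map and score neighborhood preservation.

Embeds planted-cluster abstracts, projects to 2-D with t-SNE and UMAP, and
compares the two layouts with the map-quality metrics: k-NN accuracy (do
externally derived labels survive the projection?) and k-NN recall (what
fraction of each point's 10 high-dimensional nearest neighbors stays among
its 10 nearest map neighbors?).
"""

import numpy as np

from litmap import (
    SyntheticSpec,
    classify_corpus,
    generate_cluster_embeddings,
    generate_corpus,
    knn_accuracy,
    knn_recall,
    project_2d,
)

generated = generate_corpus(
    SyntheticSpec(n_topics=4, docs_per_topic=150, seed=0)
)
X = generate_cluster_embeddings(
    generated.ledger, d=768, separation=10.0, seed=0
)
labels, _ = classify_corpus(generated.corpus)
labels = np.asarray(labels)
print(f"{X.shape[0]} abstracts embedded in {X.shape[1]} dimensions")

for method in ("tsne", "umap"):
    projection = project_2d(X, method, random_state=42)
    recall = knn_recall(X, projection, k=10)
    accuracy = knn_accuracy(
        projection, labels, k=10, test_fraction=0.05,
        exclude_label="unclassified",
    )
    print(f"{method}: k-NN accuracy = {accuracy.value:.2f}, "
          f"k-NN recall = {recall.value:.2f}")

print("\nhigher recall means the 2-D map keeps more of each point's")
print("original local neighborhood; accuracy 1.0 means held-out points")
print("are perfectly classified from their 10 nearest map neighbors.")
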