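"""2-D projection of embeddings and neighborhood-preservation scoring.

Two complementary map-quality metrics are implemented:

* **k-NN accuracy** — hold out a small test fraction of points, train a
  k-nearest-neighbor classifier on the 2-D coordinates with external labels
  (e.g. journal-derived research fields), and measure held-out accuracy.
  This asks whether label structure survives the projection.
* **k-NN recall** — for every point, find its k Euclidean nearest neighbors
  in the original high-dimensional space and in the 2-D map, and average the
  fraction of shared neighbors: ``sum_i |NN_k_high(i) ∩ NN_k_low(i)| / (n·k)``.
  This is label-free local neighborhood preservation; it equals 1 when the
  map is a rigid transform of the original space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

DEFAULT_K = 10
PROJECTION_METHODS = ("tsne", "umap")


@dataclass(frozen=True)
class Projection:
    """An ``(n, 2)`` layout plus the method tag and parameters that made it."""

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("projection coordinates must have shape (n, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("projection contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class NeighborhoodScore:
    """A neighborhood-preservation score in [0, 1]."""

    value: float
    k: int
    kind: str  # "accuracy" or "recall"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"score {self.value} outside [0, 1]")


def project_2d(
    embeddings: np.ndarray,
    method: str = "tsne",
    random_state: int = 42,
    **params,
) -> Projection:
    """Reduce an ``(n, d)`` embedding matrix to 2-D with t-SNE or UMAP.

    Uses ``n_components=2`` and a fixed ``random_state`` so identical inputs
    give identical layouts.  Hyperparameters that must stay below the sample
    count (t-SNE perplexity, UMAP n_neighbors) are clipped for tiny inputs so
    degenerate fixtures still produce finite coordinates.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (n, d) matrix with n >= 3")
    n = X.shape[0]
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = params.pop(
            "perplexity", min(30.0, max(1.0, (n - 1) / 3.0))
        )
        # PCA init is undefined for zero-variance input (all points equal)
        init = params.pop(
            "init", "pca" if X.var(axis=0).sum() > 0 else "random"
        )
        model = TSNE(
            n_components=2,
            random_state=random_state,
            perplexity=perplexity,
            init=init,
            **params,
        )
        used = {"perplexity": perplexity, **params}
    elif method == "umap":
        import umap

        n_neighbors = params.pop("n_neighbors", min(15, n - 1))
        # spectral initialisation needs more points than components
        init = params.pop("init", "spectral" if n > 10 else "random")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = umap.UMAP(
                n_components=2,
                random_state=random_state,
                n_neighbors=n_neighbors,
                init=init,
                **params,
            )
        used = {"n_neighbors": n_neighbors, **params}
    else:
        raise ValueError(
            f"unknown method {method!r}; expected one of {PROJECTION_METHODS}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(X)
    return Projection(
        coords=np.asarray(coords, dtype=np.float64),
        method=method,
        params={"n_components": 2, "random_state": random_state, **used},
    )


def _coords(space) -> np.ndarray:
    if isinstance(space, Projection):
        return space.coords
    return np.asarray(space, dtype=np.float64)


def knn_neighbor_sets(
    X: np.ndarray,
    k: int,
    include_self: bool = False,
    chunk: int = 512,
) -> np.ndarray:
    """Indices of the k Euclidean nearest neighbors of every row.

    Exhaustive search in row chunks; distance ties break toward the lower
    row index (stable argsort on (distance, index)).  With
    ``include_self=False`` (default) the query point is excluded from its own
    neighbor list.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    limit = k if include_self else k + 1
    if n < limit:
        raise ValueError(f"need more than {limit - 1} points for k={k}")
    out = np.empty((n, k), dtype=np.intp)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dists = cdist(X[start:stop], X)
        order = np.argsort(dists, axis=1, kind="stable")
        for row, global_row in enumerate(range(start, stop)):
            candidates = order[row]
            if not include_self:
                candidates = candidates[candidates != global_row]
            out[global_row] = candidates[:k]
    return out


def knn_recall(
    high_dim: np.ndarray,
    low_dim,
    k: int = DEFAULT_K,
    include_self: bool = False,
) -> NeighborhoodScore:
    """Neighborhood preservation between a high-dim space and its 2-D map.

    For each point the k nearest neighbors (self excluded by default) are
    computed in both spaces and the sizes of the intersections are summed;
    the score divides that sum by ``n * k``, the total number of possible
    shared neighbors.
    """
    high = np.asarray(high_dim, dtype=np.float64)
    low = _coords(low_dim)
    if high.shape[0] != low.shape[0]:
        raise ValueError("high- and low-dimensional spaces differ in rows")
    n = high.shape[0]
    if n <= k:
        raise ValueError(f"need n > k points (n={n}, k={k})")
    nn_high = knn_neighbor_sets(high, k, include_self=include_self)
    nn_low = knn_neighbor_sets(low, k, include_self=include_self)
    shared = sum(
        len(set(nn_high[i]) & set(nn_low[i])) for i in range(n)
    )
    return NeighborhoodScore(value=shared / (n * k), k=k, kind="recall")


def knn_accuracy(
    projection,
    labels,
    k: int = DEFAULT_K,
    test_fraction: float = 0.01,
    split_seed: int = 42,
    exclude_label: Optional[str] = None,
) -> NeighborhoodScore:
    """Held-out k-NN classification accuracy in the 2-D map.

    A ``test_fraction`` share of points is held out (seeded split), a k-NN
    classifier with exhaustive distance computation is fit on the remaining
    coordinates and the external labels, and accuracy is evaluated on the
    held-out points.  ``exclude_label`` drops records with that label (e.g.
    "unclassified") before splitting.
    """
    coords = _coords(projection)
    y = np.asarray(labels)
    if coords.shape[0] != y.shape[0]:
        raise ValueError("labels are not aligned to the projection")
    if exclude_label is not None:
        keep = y != exclude_label
        coords, y = coords[keep], y[keep]
    n_test = int(round(coords.shape[0] * test_fraction))
    if n_test < 1:
        raise ValueError("test split is empty; increase test_fraction")
    X_train, X_test, y_train, y_test = train_test_split(
        coords, y, test_size=test_fraction, random_state=split_seed
    )
    classifier = KNeighborsClassifier(
        n_neighbors=k, algorithm="brute", n_jobs=-1
    )
    classifier.fit(X_train, y_train)
    accuracy = float(classifier.score(X_test, y_test))
    return NeighborhoodScore(value=accuracy, k=k, kind="accuracy")


__all__ = [
    "DEFAULT_K",
    "NeighborhoodScore",
    "Projection",
    "knn_accuracy",
    "knn_neighbor_sets",
    "knn_recall",
    "project_2d",
]
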