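"""Self-organizing map clustering of taxon-group prevalence profiles.

Each protein family is summarised by its prevalence vector across the taxon
groups (five features by default).  A batch self-organizing map quantizes the
profiles onto a small grid of codebook vectors; the codebook is then clustered
with k-means, the number of clusters picked by the elbow heuristic, and each
cluster called into a biological category from its mean profile: pan-cellular
(broadly distributed across cellular life), true vESP (essentially restricted
to eukaryotes and viruses), or archaea-vESP (shared by eukaryotes and
archaea/Asgards but absent from bacteria).

The batch SOM update is deterministic given a seed: every epoch assigns each
profile to its best-matching unit (BMU, minimum Euclidean distance) and then
replaces every codebook vector with the Gaussian-neighborhood-weighted mean of
all profiles, the neighborhood radius decaying linearly from half the grid
diameter to 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .occurrence import GROUPS

CATEGORIES = ("pan_cellular", "true_vesp", "archaea_vesp", "other")


class SelfOrganizingMap:
    """Batch-trained SOM with a rectangular grid.

    Parameters
    ----------
    rows, cols
        Grid dimensions.  If omitted, the smallest square grid with at least
        ``5 * sqrt(n_samples)`` nodes is used, capped at 10x10.
    epochs
        Number of batch assignment/update sweeps.
    seed
        Seed for codebook initialisation (sampling of data points).
    """

    def __init__(
        self,
        rows: int | None = None,
        cols: int | None = None,
        epochs: int = 50,
        seed: int = 42,
    ) -> None:
        if rows is not None and rows < 1 or cols is not None and cols < 1:
            raise ValueError("grid dimensions must be positive")
        self.rows = rows
        self.cols = cols
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.codebook_: np.ndarray | None = None
        self._grid: np.ndarray | None = None

    @staticmethod
    def default_grid_side(n_samples: int) -> int:
        """Side of the default square grid: ceil(sqrt(5*sqrt(N))), max 10."""
        nodes = 5.0 * math.sqrt(max(n_samples, 1))
        return max(1, min(10, math.ceil(math.sqrt(nodes))))

    def _resolve_grid(self, n_samples: int) -> tuple[int, int]:
        if self.rows is None or self.cols is None:
            side = self.default_grid_side(n_samples)
            return side, side
        return self.rows, self.cols

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training data must be a non-empty 2-D array")
        if not np.isfinite(X).all():
            raise ValueError("training data contains non-finite values")
        rows, cols = self._resolve_grid(X.shape[0])
        self.rows_, self.cols_ = rows, cols
        n_nodes = rows * cols
        grid = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
        # squared grid distances between nodes
        gd2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)

        # train on a lexicographically sorted copy so the fit is exactly
        # invariant to the order profiles arrive in (float summation order
        # included); BMU prediction afterwards uses the caller's order
        Xs = X[np.lexsort(X.T[::-1])]

        rng = np.random.default_rng(self.seed)
        init_idx = rng.integers(0, Xs.shape[0], size=n_nodes)
        codebook = Xs[init_idx].copy()
        self.initial_codebook_ = codebook.copy()

        r_max = max(rows, cols) / 2.0
        r_min = 0.5
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            radius = r_max + (r_min - r_max) * frac
            bmu = self._bmu_of(Xs, codebook)
            h = np.exp(-gd2 / (2.0 * radius * radius))  # node x node
            weights = h[:, bmu]  # node x sample
            denom = weights.sum(axis=1)
            numer = weights @ Xs
            ok = denom > 1e-12
            codebook[ok] = numer[ok] / denom[ok, None]
        # zero-radius refinement: occupied nodes move to the plain mean of
        # their assigned profiles (a Lloyd step), sharpening quantization
        # after the smoothed epochs
        bmu = self._bmu_of(Xs, codebook)
        for node in np.unique(bmu):
            codebook[node] = Xs[bmu == node].mean(axis=0)
        self.codebook_ = codebook
        self._grid = grid
        return self

    @staticmethod
    def _bmu_of(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit index for each sample."""
        if self.codebook_ is None:
            raise RuntimeError("SOM is not trained")
        return self._bmu_of(np.asarray(X, float), self.codebook_)

    def quantization_error(self, X: np.ndarray, codebook: np.ndarray | None = None) -> float:
        """Mean Euclidean distance of samples to their best-matching unit."""
        X = np.asarray(X, float)
        cb = codebook if codebook is not None else self.codebook_
        if cb is None:
            raise RuntimeError("SOM is not trained")
        d2 = ((X[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.min(axis=1)).mean())


@dataclass
class ElbowCurve:
    """Within-cluster sum of squares over a range of k, and the elbow pick."""

    k_values: list[int]
    wcss: list[float]
    selected_k: int
    second_differences: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "wcss": self.wcss})


def kmeans_wcss(
    X: np.ndarray,
    k: int,
    restarts: int = 20,
    seed: int = 42,
    sample_weight: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Best-of-restarts k-means; returns (wcss, labels)."""
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(np.asarray(X, float), sample_weight=sample_weight)
    return float(km.inertia_), labels


def elbow_select(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    restarts: int = 20,
    seed: int = 42,
    sample_weight: np.ndarray | None = None,
) -> ElbowCurve:
    """Pick the number of clusters by the maximum-curvature elbow heuristic.

    k-means (best of ``restarts`` initialisations) is run for every k in
    ``[k_min, k_max]``; the selected k maximises the second forward difference
    of the WCSS curve, ``wcss[k-1] - 2*wcss[k] + wcss[k+1]``, ties broken to
    the smallest k.  When the curve carries no curvature signal (all second
    differences non-positive, or a flat curve), the fallback is ``k_min``.
    """
    X = np.asarray(X, float)
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k_max >= n_distinct:
        raise ValueError(
            f"k_max={k_max} must be smaller than the number of distinct "
            f"points ({n_distinct})"
        )
    ks = list(range(k_min, k_max + 1))
    wcss = [kmeans_wcss(X, k, restarts, seed, sample_weight)[0] for k in ks]
    scale = max(wcss[0], 1e-12)
    d2 = {
        ks[i]: wcss[i - 1] - 2.0 * wcss[i] + wcss[i + 1]
        for i in range(1, len(ks) - 1)
    }
    if not d2 or max(d2.values()) <= 1e-9 * scale:
        selected = k_min
    else:
        best = max(d2.values())
        selected = min(k for k, v in d2.items() if v == best)
    return ElbowCurve(ks, wcss, selected, d2)


def classify_cluster_category(
    centroid: np.ndarray | pd.Series,
    high: float = 0.5,
    low: float = 0.25,
    groups: tuple[str, ...] = GROUPS,
) -> str:
    """Call a cluster centroid into a prevalence category.

    ``centroid`` is a prevalence vector over ``groups``.  A cluster is
    pan-cellular when eukaryote prevalence is high and both bacteria and at
    least one archaeal lineage are non-negligible; a true vESP cluster when
    all non-eukaryotic cellular groups are negligible; an archaea-vESP
    cluster when archaea/Asgards are non-negligible but bacteria are not.
    """
    c = pd.Series(np.asarray(centroid, float), index=list(groups))
    arch_like = c.get("archaea", 0.0) >= low or c.get("asgard", 0.0) >= low
    if c["eukaryote"] >= high:
        if c.get("bacteria", 0.0) >= low and arch_like:
            return "pan_cellular"
        if c.get("bacteria", 0.0) < low and not arch_like:
            return "true_vesp"
        if c.get("bacteria", 0.0) < low and arch_like:
            return "archaea_vesp"
    return "other"


@dataclass
class ClusteringResult:
    """Full SOM -> elbow -> k-means -> category pipeline output."""

    assignments: pd.DataFrame  # pfam, node, cluster, category
    elbow: ElbowCurve
    som: SelfOrganizingMap
    cluster_centroids: pd.DataFrame  # cluster x group mean prevalence
    cluster_categories: dict[int, str]


def cluster_profiles(
    prevalence: pd.DataFrame,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 50,
    k_min: int = 2,
    k_max: int = 10,
    restarts: int = 20,
    seed: int = 42,
    high: float = 0.5,
    low: float = 0.25,
) -> ClusteringResult:
    """Cluster per-family prevalence profiles and call cluster categories.

    The SOM quantizes the profiles; the elbow method and final k-means run on
    the *occupied* codebook vectors, weighted by how many profiles map to each
    node, so empty interpolation nodes carry no weight.  Cluster ids are
    1-based; each cluster's category is called from the mean prevalence of the
    families assigned to it.
    """
    X = prevalence.to_numpy(float)
    som = SelfOrganizingMap(rows, cols, epochs=epochs, seed=seed).fit(X)
    bmu = som.predict(X)
    occupied, counts = np.unique(bmu, return_counts=True)
    nodes = som.codebook_[occupied]
    elbow = elbow_select(
        nodes, k_min=k_min, k_max=k_max, restarts=restarts, seed=seed,
        sample_weight=counts.astype(float),
    )
    _, node_labels = kmeans_wcss(
        nodes, elbow.selected_k, restarts, seed, counts.astype(float)
    )
    label_of_node = dict(zip(occupied.tolist(), (node_labels + 1).tolist()))
    clusters = np.array([label_of_node[b] for b in bmu])
    assignments = pd.DataFrame(
        {
            "pfam": prevalence.index,
            "node": bmu,
            "cluster": clusters,
        }
    ).set_index("pfam")
    centroids = (
        pd.DataFrame(X, index=prevalence.index, columns=prevalence.columns)
        .groupby(clusters)
        .mean()
    )
    categories = {
        int(cid): classify_cluster_category(
            row.to_numpy(), high=high, low=low, groups=tuple(prevalence.columns)
        )
        for cid, row in centroids.iterrows()
    }
    assignments["category"] = [categories[c] for c in assignments["cluster"]]
    return ClusteringResult(assignments, elbow, som, centroids, categories)
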