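"""Unsupervised structure diagnostics for the normalized expression matrix.

Samples are clustered hierarchically on the Canberra metric
(``d(x, y) = sum_g |x_g - y_g| / (|x_g| + |y_g|)``, zero terms where both
coordinates are zero) with Ward's minimum-variance linkage in its
squared-dissimilarity (ward.D2) dialect.  Three statistics qualify the
result:

* Hopkins statistic H — clustering tendency; ~0.5 for spatially uniform
  data, toward 1 when structure is present (nearest-neighbor convention
  with uniform reference points in the data's bounding box).
* Cophenetic correlation — Pearson r between original pairwise distances
  and the dendrogram heights at which pairs first merge; how faithfully
  the tree summarizes the distances.
* C-index — for each candidate k, how close the within-cluster distance
  sum sits to its attainable minimum over all pair subsets of that size;
  the k minimizing it is reported as optimal.

Clustering operates on log2(normalized + 1) endogenous values by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .refnorm import NormalizedMatrix


@dataclass
class ClusterDiagnostics:
    distance_matrix: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix, n-1 merges
    hopkins_H: float
    cophenetic_r: float
    c_index_by_k: dict[int, float]
    optimal_k: int

    def summary(self) -> dict:
        return {
            "hopkins_H": self.hopkins_H,
            "cophenetic_r": self.cophenetic_r,
            "optimal_k": self.optimal_k,
            "c_index_by_k": {str(k): v for k, v in self.c_index_by_k.items()},
        }


def canberra_distances(data) -> pd.DataFrame:
    """Pairwise Canberra distances between samples.

    Accepts a NormalizedMatrix (clustered on log2(x+1) endogenous values)
    or any samples-in-rows DataFrame/array of nonnegative values.
    """
    if isinstance(data, NormalizedMatrix):
        frame = data.log_endogenous().T  # samples x genes
    else:
        frame = pd.DataFrame(data)
    if (frame.values < 0).any():
        raise ValueError("Canberra distances require nonnegative values")
    condensed = pdist(frame.values, metric="canberra")
    return pd.DataFrame(squareform(condensed), index=frame.index, columns=frame.index)


def ward_linkage(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward (ward.D2 dialect) agglomeration of a precomputed distance matrix."""
    condensed = _condensed(dist)
    n = _n_from_condensed(condensed)
    if n < 2:
        raise ValueError("need >=2 samples to cluster")
    return hierarchy.linkage(condensed, method="ward")


def _condensed(dist) -> np.ndarray:
    arr = dist.values if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if arr.ndim == 2:
        return squareform(arr, checks=False)
    return arr


def _n_from_condensed(condensed: np.ndarray) -> int:
    return int(round((1 + math.isqrt(1 + 8 * len(condensed))) / 2))


def hopkins(data, m_fraction: float = 0.1, seed: int = 0) -> float:
    """Hopkins clustering-tendency statistic (clustered data -> near 1).

    Draws ``m = max(10, ceil(m_fraction * n))`` real points without
    replacement and as many uniform points in the per-dimension bounding
    box; H = sum(u) / (sum(u) + sum(w)) where u are uniform-to-nearest-real
    distances and w real-to-nearest-other-real distances.  Fully
    degenerate data (all points identical) returns 1.0.
    """
    x = np.asarray(data, dtype=float)
    if isinstance(data, pd.DataFrame):
        x = data.values.astype(float)
    n, d = x.shape
    if n < 10:
        raise ValueError("Hopkins statistic needs >=10 samples")
    rng = np.random.default_rng(seed)
    m = min(n, max(10, math.ceil(m_fraction * n)))
    chosen = rng.choice(n, size=m, replace=False)
    lo, hi = x.min(axis=0), x.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(m, d))

    tree = cKDTree(x)
    w, _ = tree.query(x[chosen], k=2)
    w = w[:, 1]  # nearest *other* real point
    u, _ = tree.query(uniform, k=1)
    total = float(u.sum() + w.sum())
    if total == 0.0:
        return 1.0
    return float(u.sum() / total)


def cophenetic_correlation(dist, linkage: np.ndarray) -> float:
    """Pearson r between original and cophenetic (merge-height) distances."""
    condensed = _condensed(dist)
    if _n_from_condensed(condensed) < 3:
        raise ValueError("cophenetic correlation undefined for n < 3")
    coph = hierarchy.cophenet(linkage)
    return float(pearsonr(condensed, coph).statistic)


def c_index(dist, labels) -> float:
    """Hubert–Levin C-index of one partition against a distance matrix."""
    condensed = _condensed(dist)
    labels = np.asarray(labels)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0:
        raise ValueError("partition has no within-cluster pairs")
    s_w = float(condensed[within].sum())
    ordered = np.sort(condensed)
    s_min = float(ordered[:n_w].sum())
    s_max = float(ordered[-n_w:].sum())
    if s_max == s_min:
        raise ValueError("all pairwise distances equal; C-index undefined")
    return (s_w - s_min) / (s_max - s_min)


def c_index_optimal_k(dist, linkage: np.ndarray,
                      k_range=range(2, 11)) -> tuple[dict[int, float], int]:
    """C-index across tree cuts; the argmin k (smallest k on ties) is optimal."""
    condensed = _condensed(dist)
    n = _n_from_condensed(condensed)
    by_k: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        by_k[k] = c_index(condensed, labels)
    if not by_k:
        raise ValueError("no feasible k in range")
    optimal = min(by_k.items(), key=lambda t: (t[1], t[0]))[0]
    return by_k, optimal


def cluster_diagnostics(norm: NormalizedMatrix, kmax: int = 10,
                        seed: int = 0) -> ClusterDiagnostics:
    """Distance matrix, Ward tree and the three validation statistics."""
    dist = canberra_distances(norm)
    link = ward_linkage(dist)
    h = hopkins(norm.log_endogenous().T, seed=seed)
    r = cophenetic_correlation(dist, link)
    by_k, optimal = c_index_optimal_k(dist, link, range(2, kmax + 1))
    return ClusterDiagnostics(
        distance_matrix=dist,
        linkage=link,
        hopkins_H=h,
        cophenetic_r=r,
        c_index_by_k=by_k,
        optimal_k=optimal,
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
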