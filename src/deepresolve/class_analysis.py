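"""Class-level structure from per-class channel importance vectors.

Multi-task networks reuse channels across tasks, and a task often learns
*negative* weights on channels that detect a competing class's motifs (a
process of elimination). Raw OFIV correlation therefore understates feature
sharing; clamping negatives to zero before correlating keeps only the
features a class genuinely favors. The resulting class similarity matrix

    A[i, j] = Pearson( clamp(OFIV_i), clamp(OFIV_j) )

captures shared sequence determinants even between classes whose labels are
mutually exclusive. Comparison modes (label correlation, unclamped OFIV
correlation, last-layer weight cosine) are provided because they famously do
*not* recover this sharing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform


def nonneg(ofiv: np.ndarray) -> np.ndarray:
    """Clamp negative entries to zero (keep only favored features)."""
    return np.maximum(np.asarray(ofiv, dtype=float), 0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else np.nan


@dataclass
class ClassSimilarityMatrix:
    """Symmetric C x C correlation matrix with class names."""

    values: np.ndarray
    names: list[str]

    def __getitem__(self, ij) -> float:
        return float(self.values[ij])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def class_similarity(ofivs: np.ndarray, names: list[str] | None = None,
                     clamp: bool = True) -> ClassSimilarityMatrix:
    """Pairwise Pearson correlation of (clamped) per-class OFIVs.

    ``clamp=False`` gives the confounded variant in which negative
    elimination terms depress similarity between pattern-sharing classes.
    Classes whose clamped vector has zero variance get NaN rows/columns
    (with a warning) rather than an arbitrary value.
    """
    ofivs = np.asarray(ofivs, dtype=float)
    if ofivs.ndim != 2 or ofivs.shape[0] < 2:
        raise ValueError("need a (C>=2, K) array of OFIVs")
    vecs = nonneg(ofivs) if clamp else ofivs
    C = vecs.shape[0]
    degenerate = [i for i in range(C) if np.ptp(vecs[i]) == 0]
    if degenerate:
        warnings.warn(f"zero-variance OFIV after clamping for classes "
                      f"{degenerate}; similarity undefined", stacklevel=2)
    A = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            if i in degenerate or j in degenerate:
                A[i, j] = A[j, i] = np.nan
            else:
                A[i, j] = A[j, i] = _pearson(vecs[i], vecs[j])
    for i in degenerate:
        A[i, i] = np.nan
    names = names or [f"class{i + 1}" for i in range(C)]
    return ClassSimilarityMatrix(values=A, names=names)


def label_correlation(labels: np.ndarray,
                      names: list[str] | None = None) -> ClassSimilarityMatrix:
    """Pearson correlation of label columns — the conventional comparison."""
    labels = np.asarray(labels, dtype=float)
    C = labels.shape[1]
    A = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            A[i, j] = A[j, i] = _pearson(labels[:, i], labels[:, j])
    return ClassSimilarityMatrix(A, names or [f"class{i+1}" for i in range(C)])


def last_layer_cosine(model, names: list[str] | None = None) -> ClassSimilarityMatrix:
    """Cosine similarity of the output-layer weight rows, per class pair."""
    Wout = model.params["W3"].T                    # (C, fc_units)
    C = Wout.shape[0]
    A = np.eye(C)
    norms = np.linalg.norm(Wout, axis=1)
    for i in range(C):
        for j in range(i + 1, C):
            A[i, j] = A[j, i] = float(Wout[i] @ Wout[j] / (norms[i] * norms[j]))
    return ClassSimilarityMatrix(A, names or [f"class{i+1}" for i in range(C)])


def class_difference(ofiv_i: np.ndarray, ofiv_j: np.ndarray) -> np.ndarray:
    """Elementwise OFIV_i - OFIV_j: features favored by i but not by j."""
    ofiv_i, ofiv_j = np.asarray(ofiv_i), np.asarray(ofiv_j)
    if ofiv_i.shape != ofiv_j.shape:
        raise ValueError("OFIV length mismatch")
    return ofiv_i - ofiv_j


def strong_counts(A: ClassSimilarityMatrix | np.ndarray,
                  targets: list[int] | None = None,
                  q_hi: float = 0.85, q_lo: float = 0.15
                  ) -> dict[int, tuple[int, int]]:
    """Per-class counts of strong positive / strong negative similarities.

    Thresholds are the *q_hi* and *q_lo* quantiles of all off-diagonal
    entries of the designated sub-matrix; strict inequalities are used.
    """
    if not 0 <= q_lo < q_hi <= 1:
        raise ValueError("need 0 <= q_lo < q_hi <= 1")
    values = A.values if isinstance(A, ClassSimilarityMatrix) else np.asarray(A)
    C = values.shape[0]
    targets = list(range(C)) if targets is None else list(targets)
    if not targets:
        raise ValueError("empty target class set")
    off = np.array([values[i, j] for i in targets for j in range(C) if j != i])
    hi = np.quantile(off, q_hi)
    lo = np.quantile(off, q_lo)
    out = {}
    for i in targets:
        row = np.array([values[i, j] for j in range(C) if j != i])
        out[i] = (int(np.sum(row > hi)), int(np.sum(row < lo)))
    return out


@dataclass
class ClassClustering:
    linkage_matrix: np.ndarray
    names: list[str]
    flat: np.ndarray

    def newick(self) -> str:
        """Dendrogram in Newick format with merge heights as branch lengths."""
        tree = to_tree(self.linkage_matrix)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.names[node.id]}:{length:.6g}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{length:.6g}")
        return (f"({rec(tree.left, tree.dist)},"
                f"{rec(tree.right, tree.dist)});")


def cluster_classes(A: ClassSimilarityMatrix | np.ndarray,
                    method: str = "average",
                    n_clusters: int = 2) -> ClassClustering:
    """Agglomerative clustering of classes at distance 1 - A."""
    if isinstance(A, ClassSimilarityMatrix):
        values, names = A.values, A.names
    else:
        values = np.asarray(A)
        names = [f"class{i + 1}" for i in range(values.shape[0])]
    if np.any(~np.isfinite(values)):
        raise ValueError("similarity matrix has undefined entries; drop the "
                         "affected classes before clustering")
    D = 1.0 - values
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClassClustering(linkage_matrix=Z, names=list(names), flat=flat)
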