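"""Hierarchical clustering of frequency profiles and cross-platform
agreement statistics.

Clustering uses (1 - Pearson correlation) as the pairwise distance and
average (UPGMA) agglomeration; agreement between two log2-ratio tables is
summarized by Spearman/Pearson correlation plus directional concordance
(the fraction of genes whose up/down direction agrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr


@dataclass
class Dendrogram:
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    leaf_labels: list[str]
    metric: str = "1 - pearson"
    linkage_method: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2]


def pearson_distance_matrix(freq_matrix: np.ndarray) -> np.ndarray:
    """d(a, b) = 1 - r(a, b) between rows; zero-variance rows sit at
    distance 1 from everything (uncorrelated) and 0 from themselves."""
    X = np.asarray(freq_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes x groups matrix with >= 2 groups")
    n = X.shape[0]
    sd = X.std(axis=1)
    degenerate = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.where(degenerate, 1.0, norms)
    U = Xc / safe[:, None]
    R = U @ U.T
    D = 1.0 - R
    D[degenerate, :] = 1.0
    D[:, degenerate] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return D


def cluster_average(
    dist: np.ndarray, leaf_labels: Sequence[str] | None = None
) -> Dendrogram:
    """UPGMA dendrogram from a symmetric distance matrix."""
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if leaf_labels is None:
        leaf_labels = [str(i) for i in range(D.shape[0])]
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(merges=Z, leaf_labels=list(leaf_labels))


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut into k clusters by undoing the k-1 highest merges.

    Returns integer labels (1..k) per leaf.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return fcluster(dendrogram.merges, t=k, criterion="maxclust")


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization with branch lengths from merge heights.

    Leaf ordering within each merge is deterministic: the subtree with the
    smaller minimum leaf label comes first.
    """
    Z = dendrogram.merges
    n = dendrogram.n_leaves
    labels = dendrogram.leaf_labels

    # node -> (newick string, height, min leaf label)
    nodes: dict[int, tuple[str, float, str]] = {
        i: (labels[i], 0.0, labels[i]) for i in range(n)
    }
    for idx in range(Z.shape[0]):
        a, b, h = int(Z[idx, 0]), int(Z[idx, 1]), float(Z[idx, 2])
        sa, ha, ma = nodes.pop(a)
        sb, hb, mb = nodes.pop(b)
        if mb < ma:
            (sa, ha, ma), (sb, hb, mb) = (sb, hb, mb), (sa, ha, ma)
        branch_a = max(0.0, h - ha)
        branch_b = max(0.0, h - hb)
        nodes[n + idx] = (
            f"({sa}:{branch_a:.6g},{sb}:{branch_b:.6g})", h, ma,
        )
    (tree, _, _), = nodes.values()
    return tree + ";"


def log2_ratio_table(
    f_stress: Sequence[float], f_control: Sequence[float], pseudo: float = 0.5
) -> np.ndarray:
    """Per-gene log2((f_s + pseudo) / (f_c + pseudo))."""
    fs = np.asarray(f_stress, dtype=float)
    fc = np.asarray(f_control, dtype=float)
    if fs.shape != fc.shape:
        raise ValueError("frequency vectors must align")
    if np.any(fs < 0) or np.any(fc < 0):
        raise ValueError("frequencies must be non-negative")
    if pseudo <= 0 and (np.any(fs == 0) or np.any(fc == 0)):
        raise ValueError("pseudo-count must be positive when zero frequencies occur")
    return np.log2((fs + pseudo) / (fc + pseudo))


@dataclass
class ConcordanceReport:
    n: int
    spearman_r: float
    pearson_r: float
    concordance: float
    quadrants: dict[str, int]  # "++", "+-", "-+", "--"
    n_zero_excluded: int = 0


def concordance(
    ratios_a: Sequence[float], ratios_b: Sequence[float]
) -> ConcordanceReport:
    """Directional agreement between two paired log-ratio vectors.

    Genes with an exactly-zero ratio on either axis have undefined sign and
    are excluded from the quadrant counts (reported separately); the
    correlations are computed over the same retained set.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratio vectors must be aligned 1-D arrays")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ratios must be finite")
    nonzero = (a != 0) & (b != 0)
    n_excluded = int((~nonzero).sum())
    a, b = a[nonzero], b[nonzero]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 nonzero pairs for correlations")
    quadrants = {
        "++": int(np.sum((a > 0) & (b > 0))),
        "+-": int(np.sum((a > 0) & (b < 0))),
        "-+": int(np.sum((a < 0) & (b > 0))),
        "--": int(np.sum((a < 0) & (b < 0))),
    }
    conc = (quadrants["++"] + quadrants["--"]) / n
    sp = float(spearmanr(a, b).statistic)
    pe = float(pearsonr(a, b).statistic)
    if math.isnan(sp):  # constant vector after exclusion
        sp = 0.0
    if math.isnan(pe):
        pe = 0.0
    return ConcordanceReport(
        n=n, spearman_r=sp, pearson_r=pe, concordance=conc,
        quadrants=quadrants, n_zero_excluded=n_excluded,
    )
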