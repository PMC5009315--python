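"""Hierarchical clustering of samples or genes restricted to a signature.

Expression heat-map clustering in the classic microarray style: Pearson
correlation distance (1 - r) with average linkage by default, Euclidean
distance and complete linkage available. A dendrogram cut into k clusters
yields a *separation score* — the weighted majority-label purity — used to
quantify how well (or how poorly) a gene signature separates known tissue
classes. Dendrograms export to Newick, reordered matrices to TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expr_io import ExpressionStudy
from .meta_signature import DirectionalGeneSet

__all__ = [
    "Dendrogram",
    "SeparationScore",
    "hierarchical_cluster",
    "separation_score",
    "export_ordered_matrix",
    "export_newick",
    "to_newick",
]

CORRELATION = "correlation"
EUCLIDEAN = "euclidean"
_METRICS = (CORRELATION, EUCLIDEAN)
_LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """A binary merge tree over labelled items.

    linkage_matrix is the standard (n-1) x 4 agglomeration record
    (children, merge height, cluster size); merge heights are nondecreasing
    for the linkages offered here.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix does not match the number of leaves")
        heights = self.linkage_matrix[:, 2]
        if (np.diff(heights) < -1e-12).any():
            raise ValueError("merge heights must be nondecreasing")
        if (heights < -1e-12).any():
            raise ValueError("merge heights must be nonnegative")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        """Labels in dendrogram display order."""
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment after cutting at the k-1 highest merges."""
        if k < 1 or k > self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}], got {k}")
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, flat)}


@dataclass(frozen=True)
class SeparationScore:
    """Weighted majority-label purity of a k-cluster cut (1 = perfect)."""

    k: int
    purity: float


def _item_matrix(
    study: ExpressionStudy,
    gene_subset: DirectionalGeneSet | None,
    axis: str,
    center_rows: bool,
) -> tuple[np.ndarray, list[str]]:
    if axis not in ("samples", "genes"):
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if gene_subset is not None:
        keep = [i for i, f in enumerate(study.feature_ids) if f in gene_subset]
        if not keep:
            raise ValueError("gene subset does not intersect the study's features")
        values = study.values[keep, :]
        features = [study.feature_ids[i] for i in keep]
    else:
        values = study.values
        features = list(study.feature_ids)
    if center_rows:
        values = values - np.median(values, axis=1, keepdims=True)
    if axis == "samples":
        return values.T, list(study.sample_ids)
    return values, features


def hierarchical_cluster(
    study: ExpressionStudy,
    gene_subset: DirectionalGeneSet | None = None,
    axis: str = "samples",
    metric: str = CORRELATION,
    linkage: str = "average",
    center_rows: bool = False,
) -> Dendrogram:
    """Agglomerative clustering of samples (or genes) on a gene subset.

    correlation distance = 1 - Pearson r between item profiles; an item
    with a constant profile has no defined correlation and is rejected by
    id. center_rows subtracts each gene's median across samples before
    clustering (display-style normalization to the row midpoint).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    items, labels = _item_matrix(study, gene_subset, axis, center_rows)
    if items.shape[0] < 2:
        raise ValueError("need >= 2 items on the clustered axis")
    if items.shape[1] < 2:
        raise ValueError("need >= 2 features on the profiling axis")
    if metric == CORRELATION:
        constant = np.isclose(items.var(axis=1), 0.0)
        if constant.any():
            bad = labels[int(np.argmax(constant))]
            raise ValueError(
                f"item {bad!r} has a constant profile; correlation distance is undefined"
            )
    d = pdist(items, metric=metric)
    # correlation distance can go microscopically negative in floating point
    z = hierarchy.linkage(np.clip(d, 0.0, None), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=labels)


def separation_score(dend: Dendrogram, labels: dict[str, str], k: int = 2) -> SeparationScore:
    """Majority-label purity of the k-cluster cut of a dendrogram.

    purity = sum over clusters of the majority-class count, divided by the
    total number of items; 1.0 means every cluster is single-class.
    """
    missing = [l for l in dend.labels if l not in labels]
    if missing:
        raise ValueError(f"leaves without a class label: {missing}")
    if k > dend.n_leaves:
        raise ValueError(f"k={k} exceeds the number of leaves ({dend.n_leaves})")
    assignment = dend.cut(k)
    clusters: dict[int, list[str]] = {}
    for leaf, c in assignment.items():
        clusters.setdefault(c, []).append(labels[leaf])
    majority_total = 0
    for members in clusters.values():
        counts: dict[str, int] = {}
        for m in members:
            counts[m] = counts.get(m, 0) + 1
        majority_total += max(counts.values())
    return SeparationScore(k=k, purity=majority_total / dend.n_leaves)


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths = height differences to the parent."""
    tree = hierarchy.to_tree(dend.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = repr(float(parent_height - node.dist))
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{length}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length}"

    return render(tree, tree.dist) + ";"


def export_newick(dend: Dendrogram, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(to_newick(dend) + "\n")


def export_ordered_matrix(
    study: ExpressionStudy,
    path,
    dend_rows: Dendrogram | None = None,
    dend_cols: Dendrogram | None = None,
) -> None:
    """Write the matrix TSV with rows/columns reordered by dendrogram leaves.

    Either dendrogram may be omitted (that axis keeps its input order); a
    supplied dendrogram must label exactly the corresponding axis.
    """
    row_order = list(study.feature_ids)
    col_order = list(study.sample_ids)
    if dend_rows is not None:
        if set(dend_rows.labels) != set(study.feature_ids):
            raise ValueError("row dendrogram leaves do not match the study's features")
        row_order = dend_rows.leaf_order
    if dend_cols is not None:
        if set(dend_cols.labels) != set(study.sample_ids):
            raise ValueError("column dendrogram leaves do not match the study's samples")
        col_order = dend_cols.leaf_order
    frame = study.to_frame().loc[row_order, col_order]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(col_order) + "\n")
        for fid, row in zip(frame.index, frame.to_numpy()):
            fh.write(str(fid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
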