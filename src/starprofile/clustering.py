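"""Expression clustering with Cluster 3.0 semantics and file outputs.

The protocol: exact zeros (undetected, not unexpressed) are replaced by a
small positive floor; each gene row is median-centered (repeatedly) and
scaled so its sum of squares is 1; genes and stages are clustered by
centroid-linkage agglomeration under a correlation distance; and the ordered
matrix plus both dendrograms are written as the CDT/GTR/ATR triplet that
Java TreeView renders as the familiar green-black-red heat map.

Centroid linkage here means: the distance between two clusters is the metric
distance between the arithmetic means of their members' processed profiles.
It is implemented directly (rather than via a linkage library) because the
correlation-distance centroid rule and the deterministic tie-breaks below
are not expressible through standard Euclidean-only centroid linkage.
Merge-height inversions, which centroid linkage permits, are emitted as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ConsistencyError, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Matrix preparation
# ---------------------------------------------------------------------------

def replace_zeros(matrix: pd.DataFrame, eps: float = 0.0002) -> pd.DataFrame:
    """Replace exact zeros with a small positive floor; idempotent."""
    if eps <= 0:
        raise ParameterError("eps must be positive")
    out = matrix.copy()
    out[out == 0] = eps
    return out


def center_and_normalize(
    matrix: pd.DataFrame, center_passes: int = 3, norm_passes: int = 5
) -> pd.DataFrame:
    """Row-wise median centering then sum-of-squares normalization.

    After all passes every surviving row has median 0 and sum of squares 1.
    A constant row becomes all-zero under centering and cannot be normalized;
    such rows are dropped with a logged warning.
    """
    out = matrix.astype(float).copy()
    constant = out.nunique(axis=1) == 1
    if constant.any():
        dropped = list(out.index[constant])
        logger.warning("dropping %d constant row(s): %s", len(dropped), dropped[:10])
        out = out[~constant]
    arr = out.to_numpy()
    for _ in range(center_passes):
        arr = arr - np.median(arr, axis=1, keepdims=True)
    for _ in range(norm_passes):
        ss = np.sqrt((arr**2).sum(axis=1, keepdims=True))
        arr = arr / ss
    return pd.DataFrame(arr, index=out.index, columns=out.columns)


# ---------------------------------------------------------------------------
# Centroid-linkage agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """An agglomeration over ``ids``: scipy-style merge list.

    Leaves are numbered 0..n-1 in ``ids`` order; the t-th merge creates node
    ``n + t`` joining nodes ``a`` and ``b`` at ``height``.
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


def _distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "pearson":
        uc, vc = u - u.mean(), v - v.mean()
        denom = np.linalg.norm(uc) * np.linalg.norm(vc)
        return 1.0 if denom == 0 else max(float(1.0 - (uc @ vc) / denom), 0.0)
    if metric == "uncentered":
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        return 1.0 if denom == 0 else max(float(1.0 - (u @ v) / denom), 0.0)
    raise ParameterError(f"unknown metric {metric!r}")


def _pairwise(X: np.ndarray, metric: str) -> np.ndarray:
    """Full pairwise distance matrix for the initial singleton clusters."""
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        return cdist(X, X)
    if metric == "pearson":
        sd = X.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        D = np.maximum(1.0 - C, 0.0)
        bad = sd == 0
        D[bad, :] = 1.0
        D[:, bad] = 1.0
        return D
    if metric == "uncentered":
        norms = np.linalg.norm(X, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        Xn = X / safe[:, None]
        D = np.maximum(1.0 - Xn @ Xn.T, 0.0)
        bad = norms == 0
        D[bad, :] = 1.0
        D[:, bad] = 1.0
        return D
    raise ParameterError(f"unknown metric {metric!r}")


def centroid_hclust(matrix: pd.DataFrame, axis: str = "rows", metric: str = "pearson") -> Tree:
    """Agglomerative centroid-linkage clustering of rows or columns.

    At each step the pair of clusters with the smallest centroid-to-centroid
    distance merges; a cluster's centroid is the arithmetic mean of its
    members' profiles. Distance ties break deterministically toward the pair
    with the lexicographically smallest (item-id, item-id) key, where a
    cluster is keyed by its smallest member id.
    """
    data = matrix if axis == "rows" else matrix.T
    ids = [str(i) for i in data.index]
    X = data.to_numpy(float)
    n = len(ids)
    if n < 2:
        raise ParameterError("need at least 2 items to cluster")

    total = 2 * n - 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: ids[i] for i in range(n)}  # smallest member id
    centroids = np.full((total, X.shape[1]), np.nan)
    centroids[:n] = X
    D = np.full((total, total), np.inf)
    P = _pairwise(X, metric)
    D[:n, :n] = np.minimum(P, P.T)  # enforce bit-exact symmetry
    D[np.arange(n), np.arange(n)] = np.inf

    alive = np.zeros(total, dtype=bool)
    alive[:n] = True
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = D[np.ix_(alive, alive)]
        d_min = sub.min()
        idx = np.flatnonzero(alive)
        ii, jj = np.nonzero(np.isclose(sub, d_min, rtol=0, atol=0))
        # candidate pairs at the exact minimum; tie-break by smallest id pair
        best = None
        for i_loc, j_loc in zip(ii, jj):
            if i_loc == j_loc:
                continue
            a, b = sorted((int(idx[i_loc]), int(idx[j_loc])))
            pair = tuple(sorted((rep[a], rep[b])))
            if best is None or pair < best[0]:
                best = (pair, a, b)
        _pair, a, b = best
        merges.append((a, b, float(d_min)))
        new = n + step
        members[new] = members[a] + members[b]
        rep[new] = min(rep[a], rep[b])
        centroids[new] = X[members[new]].mean(axis=0)
        alive[a] = alive[b] = False
        others = np.flatnonzero(alive)
        for other in others:
            D[new, other] = D[other, new] = _distance(
                centroids[new], centroids[other], metric
            )
        alive[new] = True
    return Tree(ids=ids, merges=merges)


def cut_tree(tree: Tree, k: int) -> pd.Series:
    """Labels from cutting the agglomeration at ``k`` clusters (first n-k merges)."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _h) in enumerate(tree.merges[: n - k]):
        node = n + t
        parent[find(a)] = node
        parent[find(b)] = node
    roots = {find(i) for i in range(n)}
    relabel = {r: i for i, r in enumerate(sorted(roots))}
    return pd.Series([relabel[find(i)] for i in range(n)], index=tree.ids, name="cluster")


# ---------------------------------------------------------------------------
# Leaf ordering and Cluster 3.0 outputs
# ---------------------------------------------------------------------------

def _node_info(tree: Tree):
    n = tree.n_leaves
    children = {n + t: (a, b) for t, (a, b, _h) in enumerate(tree.merges)}
    height = {i: 0.0 for i in range(n)}
    for t, (_a, _b, h) in enumerate(tree.merges):
        height[n + t] = h
    min_leaf = {i: tree.ids[i] for i in range(n)}
    for t, (a, b, _h) in enumerate(tree.merges):
        min_leaf[n + t] = min(min_leaf[a], min_leaf[b])
    return children, height, min_leaf


def leaf_order(tree: Tree) -> list[int]:
    """Leaf permutation by recursive traversal, tighter-merging subtree first.

    At each internal node the child subtree with the smaller own merge height
    is visited first (leaves count as height 0); ties break by smallest
    contained item id.
    """
    children, height, min_leaf = _node_info(tree)
    root = tree.n_leaves + len(tree.merges) - 1
    order: list[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            order.append(node)
        else:
            a, b = children[node]
            first, second = sorted((a, b), key=lambda c: (height[c], min_leaf[c]))
            stack.extend([second, first])  # LIFO: `first` is visited first
    return order


def order_matrix(matrix: pd.DataFrame, row_tree: Tree, col_tree: Tree | None = None) -> pd.DataFrame:
    if list(matrix.index.astype(str)) != row_tree.ids:
        raise ConsistencyError("row tree does not match matrix rows")
    rows = [row_tree.ids[i] for i in leaf_order(row_tree)]
    out = matrix.loc[rows]
    if col_tree is not None:
        if list(matrix.columns.astype(str)) != col_tree.ids:
            raise ConsistencyError("column tree does not match matrix columns")
        cols = [col_tree.ids[i] for i in leaf_order(col_tree)]
        out = out[cols]
    return out


def _node_names(tree: Tree, prefix: str):
    names = {i: f"{prefix}{i}X" for i in range(tree.n_leaves)}
    for t in range(len(tree.merges)):
        names[tree.n_leaves + t] = f"NODE{t + 1}X"
    return names


def write_gtr(tree: Tree, path: str, prefix: str = "GENE") -> None:
    """Write a Cluster 3.0 tree file (GTR/ATR): one merge per line, as similarity 1-h."""
    names = _node_names(tree, prefix)
    with open(path, "w") as fh:
        for t, (a, b, h) in enumerate(tree.merges):
            fh.write(
                f"NODE{t + 1}X\t{names[a]}\t{names[b]}\t{1.0 - h:.6f}\n"
            )


def write_cdt(
    matrix: pd.DataFrame,
    row_tree: Tree,
    col_tree: Tree | None,
    path: str,
) -> None:
    """Write the ordered matrix in the Cluster 3.0 CDT dialect.

    Rows/columns are ordered by the trees' leaf orders; GID/AID identifiers
    reference the GTR/ATR node names, and unit GWEIGHT/EWEIGHT are emitted.
    """
    ordered = order_matrix(matrix, row_tree, col_tree)
    gid = {tree_id: f"GENE{i}X" for i, tree_id in enumerate(row_tree.ids)}
    with open(path, "w") as fh:
        cols = list(ordered.columns)
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        if col_tree is not None:
            aid = {tree_id: f"ARRY{i}X" for i, tree_id in enumerate(col_tree.ids)}
            fh.write("AID\t\t\t\t" + "\t".join(aid[c] for c in cols) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in cols) + "\n")
        for gene, row in ordered.iterrows():
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gid[str(gene)]}\t{gene}\t{gene}\t1\t{vals}\n")


def read_cdt(path: str) -> pd.DataFrame:
    """Parse a CDT written by :func:`write_cdt` back into its ordered matrix."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[4:]
        rows = {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] in ("AID", "EWEIGHT"):
                continue
            rows[parts[1]] = [float(v) for v in parts[4:]]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "gene_id"
    return df


def cluster_expression(
    matrix: pd.DataFrame,
    metric: str = "pearson",
    center_passes: int = 3,
    norm_passes: int = 5,
    zero_eps: float = 0.0002,
):
    """Full protocol: zero floor, center/normalize, cluster genes and stages.

    Returns ``(processed, row_tree, col_tree)``; write the TreeView triplet
    with :func:`write_cdt` / :func:`write_gtr`.
    """
    prepared = replace_zeros(matrix, zero_eps)
    processed = center_and_normalize(prepared, center_passes, norm_passes)
    row_tree = centroid_hclust(processed, axis="rows", metric=metric)
    col_tree = centroid_hclust(processed, axis="cols", metric=metric)
    return processed, row_tree, col_tree


def plot_heatmap(ordered: pd.DataFrame, path: str) -> None:
    """Green-black-red heat map of an ordered processed matrix (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("gbr", ["green", "black", "red"])
    lim = np.abs(ordered.to_numpy()).max()
    fig, ax = plt.subplots(figsize=(6, max(4, len(ordered) / 20)))
    ax.imshow(ordered.to_numpy(), aspect="auto", cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
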