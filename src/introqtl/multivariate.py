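"""Correlation-network grouping and Ward hierarchical clustering of traits.

The correlation network analysis (CNA) connects two traits when the
absolute Pearson correlation of their log2 profiles strictly exceeds a
threshold (default 0.7); groups are the connected components.  The
hierarchical clustering uses a correlation-derived distance (default
d = 1 - |r|) and an agglomerative Ward criterion implemented as the
Lance-Williams recurrence with total, deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_CNA_THRESHOLD = 0.7


@dataclass(frozen=True)
class VOCGroup:
    group_id: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Merge:
    left: int    # node ids; leaves are 0..n-1, internal nodes n, n+1, ...
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    """Binary merge tree over ``labels`` with n-1 merges, heights root-ward
    nondecreasing under Ward linkage."""

    labels: list[str]
    merges: list[Merge]

    def __post_init__(self) -> None:
        if len(self.merges) != max(len(self.labels) - 1, 0):
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for plotting interop)."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges],
            dtype=float,
        )

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order implied by the merge tree."""
        n = self.n_leaves
        if n == 1:
            return [0]
        children = {n + i: (m.left, m.right) for i, m in enumerate(self.merges)}
        order: list[int] = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return order

    def cut_k(self, k: int) -> dict[str, int]:
        """Cluster labels from cutting the k-1 highest (last) merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, m in enumerate(self.merges[: n - k]):
            node = n + i
            parent[find(m.left)] = node
            parent[find(m.right)] = node
        roots: dict[int, int] = {}
        out = {}
        for leaf in range(n):
            r = find(leaf)
            if r not in roots:
                roots[r] = len(roots)
            out[self.labels[leaf]] = roots[r]
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n_leaves
        if n == 1:
            return f"{_nwk_escape(self.labels[0])}:0;"
        height = {i: 0.0 for i in range(n)}
        text = {i: _nwk_escape(self.labels[i]) for i in range(n)}
        for i, m in enumerate(self.merges):
            node = n + i
            bl_l = m.height - height[m.left]
            bl_r = m.height - height[m.right]
            text[node] = f"({text[m.left]}:{bl_l:.6g},{text[m.right]}:{bl_r:.6g})"
            height[node] = m.height
        return text[n + len(self.merges) - 1] + ";"


def _nwk_escape(label: str) -> str:
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def pearson_matrix(log_values: pd.DataFrame) -> pd.DataFrame:
    """Trait x trait Pearson correlations; zero-variance traits get r = 0
    against everything (unit diagonal kept)."""
    if len(log_values) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    arr = log_values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=log_values.columns, columns=log_values.columns)


def correlation_graph(corr: pd.DataFrame,
                      threshold: float = DEFAULT_CNA_THRESHOLD) -> nx.Graph:
    """Simple graph with an edge where |r| strictly exceeds the threshold."""
    g = nx.Graph()
    traits = list(corr.columns)
    g.add_nodes_from(traits)
    arr = corr.to_numpy()
    n = len(traits)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(arr[i, j]) > threshold:
                g.add_edge(traits[i], traits[j], r=float(arr[i, j]))
    return g


def cna_groups(corr: pd.DataFrame,
               threshold: float = DEFAULT_CNA_THRESHOLD) -> list[VOCGroup]:
    """Connected components of the thresholded correlation graph, sorted by
    size descending then smallest member id; members sorted within a group."""
    g = correlation_graph(corr, threshold)
    comps = [tuple(sorted(c, key=str)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    return [VOCGroup(group_id=f"G{i + 1}", members=c) for i, c in enumerate(comps)]


def trait_distance(corr: pd.DataFrame, variant: str = "abs") -> pd.DataFrame:
    """Correlation-based distance: ``abs`` -> 1 - |r|; ``signed`` -> 1 - r."""
    if variant == "abs":
        d = 1.0 - corr.abs()
    elif variant == "signed":
        d = 1.0 - corr
    else:
        raise ValueError(f"unknown distance variant {variant!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d.values, 0.0)
    return d


def ward_hca(distance: pd.DataFrame, variant: str = "classic") -> Dendrogram:
    """Agglomerative Ward clustering via the Lance-Williams recurrence.

    ``classic`` applies the recurrence to the given distances (hclust
    ward.D style); ``squared`` applies it to squared distances and reports
    square-root heights (ward.D2 style, the behaviour of SciPy's ``ward``).
    Ties are broken by the lowest pair of current node ids, so the merge
    sequence is a deterministic function of the input.
    """
    arr = distance.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    if variant not in ("classic", "squared"):
        raise ValueError(f"unknown ward variant {variant!r}")
    labels = [str(c) for c in distance.columns]
    n = len(labels)
    if n == 1:
        return Dendrogram(labels=labels, merges=[])
    d = arr.astype(float).copy()
    if variant == "squared":
        d = d**2
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> size
    index: dict[int, int] = {i: i for i in range(n)}   # node id -> matrix row
    merges: list[Merge] = []
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                val = d[index[a], index[b]]
                if best is None or val < best[0] - 1e-12:
                    best = (val, a, b)
        dist_ab, a, b = best
        na, nb = active[a], active[b]
        new_id = n + step
        height = dist_ab if variant == "classic" else float(np.sqrt(dist_ab))
        merges.append(Merge(left=a, right=b, height=height, size=na + nb))
        ra, rb = index[a], index[b]
        # Lance-Williams Ward update against every other active cluster
        for c in ids:
            if c in (a, b):
                continue
            rc, nc = index[c], active[c]
            tot = na + nb + nc
            new_d = (
                (na + nc) / tot * d[ra, rc]
                + (nb + nc) / tot * d[rb, rc]
                - nc / tot * dist_ab
            )
            d[ra, rc] = d[rc, ra] = new_d
        del active[a], active[b], index[a], index[b]
        active[new_id] = na + nb
        index[new_id] = ra
    return Dendrogram(labels=labels, merges=merges)


def cluster_traits(corr: pd.DataFrame, k: int, distance_variant: str = "abs",
                   ward_variant: str = "classic") -> tuple[Dendrogram, dict[str, int]]:
    dend = ward_hca(trait_distance(corr, distance_variant), ward_variant)
    return dend, dend.cut_k(k)


def _chain_dendrogram(labels: list[str]) -> Dendrogram:
    """Zero-height left-comb tree preserving input order (degenerate input)."""
    merges = [
        Merge(left=0 if i == 0 else len(labels) + i - 1, right=i + 1,
              height=0.0, size=i + 2)
        for i in range(len(labels) - 1)
    ]
    return Dendrogram(labels=labels, merges=merges)


def two_way_order(
    log_values: pd.DataFrame,
    distance_variant: str = "abs",
    ward_variant: str = "classic",
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Cluster traits and samples with the same correlation metric and
    return both dendrograms plus the doubly reordered matrix.

    When one axis is too short to correlate over (fewer than 3 profiles on
    the other axis), that axis keeps its input order under a trivial tree.
    """
    if len(log_values) >= 3:
        trait_dend = ward_hca(
            trait_distance(pearson_matrix(log_values), distance_variant),
            ward_variant,
        )
    else:
        trait_dend = _chain_dendrogram([str(c) for c in log_values.columns])
    if log_values.shape[1] >= 3 and len(log_values) > 1:
        sample_corr = pearson_matrix(log_values.T)
        sample_dend = ward_hca(
            trait_distance(sample_corr, distance_variant), ward_variant
        )
        row_order = [sample_dend.labels[i] for i in sample_dend.leaf_order()]
    else:
        sample_dend = _chain_dendrogram([str(i) for i in log_values.index])
        row_order = list(sample_dend.labels)
    col_order = [trait_dend.labels[i] for i in trait_dend.leaf_order()]
    reordered = log_values.loc[row_order, col_order]
    return trait_dend, sample_dend, reordered


def group_cluster_concordance(
    groups: list[VOCGroup], labels: dict[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate CNA groups against clusters.

    Returns the contingency table (groups x clusters, counts) and a
    set-overlap score table (Jaccard index per group/cluster pair).
    """
    universe = {m for g in groups for m in g.members}
    if universe != set(labels):
        raise ValueError("groups and cluster labels cover different traits")
    cluster_ids = sorted(set(labels.values()))
    table = pd.DataFrame(
        0, index=[g.group_id for g in groups], columns=cluster_ids
    )
    jacc = pd.DataFrame(
        0.0, index=[g.group_id for g in groups], columns=cluster_ids
    )
    members_by_cluster = {
        c: {t for t, lab in labels.items() if lab == c} for c in cluster_ids
    }
    for g in groups:
        gm = set(g.members)
        for c in cluster_ids:
            inter = len(gm & members_by_cluster[c])
            table.loc[g.group_id, c] = inter
            union = len(gm | members_by_cluster[c])
            jacc.loc[g.group_id, c] = inter / union if union else 0.0
    return table, jacc
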