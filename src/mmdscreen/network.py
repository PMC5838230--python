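"""Control-centered MMD distance matrices, Ward clustering and the
threshold-pruned phenotype network.

Distances between knockdown populations from different experimental sets are
the square roots of the control-centered squared MMD (each sample minus its
own set's control mean embedding); same-set pairs reduce to the plain MMD.
Populations are agglomerated with Ward's criterion applied to the distances
as given (the unsquared "ward.D" update), and the phenotype network connects
pairs whose distance is at or below a pruning threshold (0.1 on the MMD
scale by default), adding edges in ascending distance order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, to_tree
from sklearn.base import BaseEstimator

from .mmd import centered_mmd_squared, mmd_squared
from .preprocessing import FeatureMatrix

NODE_SEP = ":"


def node_label(set_id: str, population_id: str) -> str:
    return f"{set_id}{NODE_SEP}{population_id}"


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric matrix of control-centered MMD distances among populations."""

    labels: list[str]  # set-qualified "set:population" labels
    matrix: np.ndarray
    bandwidth: float
    condition: str
    populations: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(m < 0) or np.any(np.diag(m) != 0):
            raise ValueError("distances must be >= 0 with a zero diagonal")
        self.matrix = m

    def to_frame(self, order: Sequence[int] | None = None) -> pd.DataFrame:
        idx = np.asarray(order if order is not None else range(len(self.labels)))
        labels = [self.labels[i] for i in idx]
        return pd.DataFrame(self.matrix[np.ix_(idx, idx)], index=labels, columns=labels)


def pairwise_centered_distances(
    fm: FeatureMatrix,
    populations: Sequence[tuple[str, str]],
    h: float,
) -> DistanceMatrix:
    """Control-centered MMD distance between every pair of listed populations.

    Entry (i, j) is sqrt(||(mu_i - mu_{A_i}) - (mu_j - mu_{A_j})||^2) with
    A_i the control of population i's experimental set; for same-set pairs
    the control terms cancel and the entry equals the plain MMD.
    """
    populations = list(populations)
    samples = [fm.values(s, p) for s, p in populations]
    controls = {}
    for set_id, _ in populations:
        if set_id not in controls:
            try:
                controls[set_id] = fm.control_values(set_id)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"missing control sample for set {set_id!r}") from exc
    n = len(populations)
    m = np.zeros((n, n))
    for i in range(n):
        set_i = populations[i][0]
        for j in range(i + 1, n):
            set_j = populations[j][0]
            if set_i == set_j:
                d2 = mmd_squared(samples[i], samples[j], h)
            else:
                d2 = centered_mmd_squared(
                    samples[i], controls[set_i], samples[j], controls[set_j], h
                )
            m[i, j] = m[j, i] = np.sqrt(d2)
    return DistanceMatrix(
        labels=[node_label(s, p) for s, p in populations],
        matrix=m,
        bandwidth=h,
        condition=fm.condition,
        populations=populations,
    )


def ward_d_linkage(distances: np.ndarray) -> np.ndarray:
    """Agglomerative Ward linkage on the dissimilarities as given (ward.D).

    Applies the Lance-Williams update
        d(ij, k) = ((n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j))
                   / (n_i + n_j + n_k)
    directly to the input dissimilarities, without squaring — the behaviour
    of R's ``hclust(method="ward.D")``. Returns a scipy-style (n-1, 4)
    linkage matrix. Ties break on the lowest cluster indices.
    """
    D = np.array(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix with >= 2 populations")
    np.fill_diagonal(D, np.inf)
    size = np.ones(n)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], D, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        lo, hi = sorted((cluster_id[i], cluster_id[j]))
        Z[step] = (lo, hi, d_ij, size[i] + size[j])
        for k in np.flatnonzero(active):
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (
                (size[i] + size[k]) * D[i, k]
                + (size[j] + size[k]) * D[j, k]
                - size[k] * d_ij
            ) / (size[i] + size[j] + size[k])
        size[i] += size[j]
        cluster_id[i] = n + step
        active[j] = False
        D[j, :] = D[:, j] = np.inf
    return Z


@dataclasses.dataclass
class ClusterResult:
    """Ward merge tree over a distance matrix, scipy linkage format."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in leaves_list(self.linkage)]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster assignment (1-based ids) at a requested cluster count."""
        return fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as node depths."""
        root = to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


class PhenotypeClustering(BaseEstimator):
    """Ward (ward.D) hierarchical clustering of an MMD distance matrix.

    Parameters
    ----------
    n_clusters : int, default 2
        Cluster count of the flat cut reported in ``labels_``.

    Attributes
    ----------
    linkage_ : ndarray of shape (n-1, 4)
        scipy-format merge tree with ward.D heights.
    labels_ : ndarray of shape (n,)
        Flat cluster ids (1-based) at the requested cut.
    leaf_order_ : list of int
        Dendrogram leaf order, for heatmap rendering.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, dm: DistanceMatrix | np.ndarray, y=None):
        if isinstance(dm, DistanceMatrix):
            matrix, names = dm.matrix, dm.labels
        else:
            matrix = np.asarray(dm, dtype=float)
            names = [str(i) for i in range(matrix.shape[0])]
        self.linkage_ = ward_d_linkage(matrix)
        self.result_ = ClusterResult(linkage=self.linkage_, labels=list(names))
        self.labels_ = self.result_.cut(self.n_clusters)
        self.leaf_order_ = self.result_.leaf_order
        return self

    def fit_predict(self, dm, y=None) -> np.ndarray:
        return self.fit(dm).labels_


def ward_cluster(dm: DistanceMatrix) -> ClusterResult:
    """Functional wrapper over :class:`PhenotypeClustering`."""
    return PhenotypeClustering().fit(dm).result_


@dataclasses.dataclass
class PhenotypeNetwork:
    """Populations as nodes, centered MMD distances <= threshold as edges."""

    graph: nx.Graph
    threshold: float
    condition: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["mmd"]) for u, v, d in self.graph.edges(data=True)]


def build_threshold_network(
    dm: DistanceMatrix, threshold: float = 0.1
) -> PhenotypeNetwork:
    """Greedy threshold network: connect the closest pair first, then the
    next, until the distance threshold; the resulting edge set equals plain
    thresholding. Isolated nodes are retained."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    for idx, label in enumerate(dm.labels):
        attrs = {}
        if dm.populations:
            attrs = {
                "set_id": dm.populations[idx][0],
                "population_id": dm.populations[idx][1],
            }
        g.add_node(label, **attrs)
    n = len(dm.labels)
    pairs = [
        (dm.matrix[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    ]
    for dist, i, j in sorted(pairs):
        if dist > threshold:
            break
        g.add_edge(dm.labels[i], dm.labels[j], mmd=float(dist))
    return PhenotypeNetwork(graph=g, threshold=threshold, condition=dm.condition)


def export_network(
    net: PhenotypeNetwork,
    out_dir: str | Path,
    *,
    stem: str = "phenotype_network",
    formats: Sequence[str] = ("graphml", "sif"),
) -> dict[str, Path]:
    """Write the network in Cytoscape-loadable formats.

    GraphML carries the ``mmd`` edge attribute; SIF uses the relation token
    ``mmd`` and lists isolated nodes on their own lines; a node-attribute TSV
    accompanies both.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    known = {"graphml", "sif"}
    unknown = set(formats) - known
    if unknown:
        raise ValueError(f"unknown format(s) {sorted(unknown)}; supported: {sorted(known)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "graphml" in formats:
        path = out_dir / f"{stem}.graphml"
        nx.write_graphml(net.graph, path)
        written["graphml"] = path
    if "sif" in formats:
        path = out_dir / f"{stem}.sif"
        lines = [f"{u}\tmmd\t{v}" for u, v, _ in net.edges]
        lines += [n for n in net.nodes if net.graph.degree(n) == 0]
        path.write_text("\n".join(lines) + "\n")
        written["sif"] = path
    attr_path = out_dir / f"{stem}.nodes.tsv"
    rows = [{"node": n, **net.graph.nodes[n]} for n in net.nodes]
    pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
    written["nodes"] = attr_path
    return written


def export_distance_matrix(
    dm: DistanceMatrix,
    path: str | Path,
    cluster: ClusterResult | None = None,
) -> Path:
    """Distance matrix as TSV, rows/columns in Ward leaf order when given."""
    order = cluster.leaf_order if cluster is not None else None
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dm.to_frame(order).to_csv(path, sep="\t")
    return path
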