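"""Co-regulation analysis (CRA): the correlation network of the most variable
genes, its cluster and sub-cluster structure, fold-change overlays, gene-set /
transcriptional-regulator mapping, and the hierarchical-clustering heatmap
orders.

Edges connect gene pairs with Pearson correlation at or above ``r_min``
(default 0.7) over *all* samples, positive correlations only — anti-correlated
programs therefore land in separate components, which is exactly how an
up-regulated and a down-regulated cluster separate.  Clusters are connected
components labeled C1, C2, ... by decreasing size; sub-clusters are greedy
modularity communities within a component, labeled a, b, ... by decreasing
size.  Tie-breaking is by smallest member gene id, so labels are stable under
input permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from scipy.cluster import hierarchy

from .containers import ExpressionMatrix
from .preprocess import FCOverlay, _require_scale

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "MappingSummary",
    "HCResult",
    "build_cra_network",
    "detect_clusters",
    "annotate_fc",
    "map_gene_set",
    "hierarchical_cluster",
]


@dataclass
class GeneNetwork:
    """Undirected gene graph with correlation-weighted edges.

    Node attributes (after the relevant annotation steps): ``cluster``,
    ``subcluster``, per-group ``fc_<group>`` log2 overlays, and boolean
    ``in_<set>`` membership flags.  Every edge carries its Pearson ``r``.
    """

    graph: nx.Graph
    r_min: float

    @property
    def genes(self) -> list[str]:
        return list(self.graph.nodes)

    def clusters(self) -> dict[str, list[str]]:
        """Cluster label -> sorted member genes (after detect_clusters)."""
        out: dict[str, list[str]] = {}
        for node, data in self.graph.nodes(data=True):
            out.setdefault(data.get("cluster", "?"), []).append(node)
        return {k: sorted(v) for k, v in sorted(out.items())}

    def subclusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, data in self.graph.nodes(data=True):
            out.setdefault(data.get("subcluster", "?"), []).append(node)
        return {k: sorted(v) for k, v in sorted(out.items())}


def build_cra_network(
    log_expr: ExpressionMatrix, genes: list[str], r_min: float = 0.7
) -> GeneNetwork:
    """Correlation network over the given genes at threshold ``r_min``.

    An edge (a, b) exists iff Pearson r(a, b) >= r_min, computed on log2
    expression over all samples.  Isolated nodes are retained; zero-variance
    genes have undefined correlations and stay isolated, with a warning.
    """
    _require_scale(log_expr, "log2cpm")
    if len(genes) < 2:
        raise ValueError("need at least two genes to build a network")
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in log_expr.values.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    X = log_expr.values.loc[genes].to_numpy(dtype=float)
    flat = X.std(axis=1) == 0
    if flat.any():
        logger.warning(
            "%d zero-variance genes have undefined correlations; kept as isolated nodes",
            int(flat.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    G = nx.Graph()
    G.add_nodes_from(sorted(genes))
    ia, ib = np.triu_indices(len(genes), k=1)
    r = R[ia, ib]
    keep = np.isfinite(r) & (r >= r_min)
    for i, j, rv in zip(ia[keep], ib[keep], r[keep]):
        G.add_edge(genes[i], genes[j], r=float(rv))
    return GeneNetwork(G, float(r_min))


def detect_clusters(network: GeneNetwork) -> GeneNetwork:
    """Label connected components C1, C2, ... and communities C1a, C1b, ...

    Components are ordered by decreasing size, ties by lexicographically
    smallest member.  Within each component, sub-clusters are greedy
    modularity communities (deterministic for a fixed graph); components with
    fewer than three nodes or no edges form a single sub-cluster.  The
    sub-cluster partition refines the component partition by construction.
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(network.graph)),
        key=lambda c: (-len(c), c[0]),
    )
    for ci, members in enumerate(comps, start=1):
        cluster = f"C{ci}"
        sub = network.graph.subgraph(members)
        if len(members) >= 3 and sub.number_of_edges() > 0:
            comms = [sorted(c) for c in greedy_modularity_communities(sub)]
            comms.sort(key=lambda c: (-len(c), c[0]))
        else:
            comms = [members]
        for si, comm in enumerate(comms):
            label = cluster + _alpha_label(si) if len(comms) > 1 else cluster + "a"
            for g in comm:
                network.graph.nodes[g]["cluster"] = cluster
                network.graph.nodes[g]["subcluster"] = label
    return network


def _alpha_label(i: int) -> str:
    # a, b, ..., z, aa, ab, ... for pathological community counts
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def annotate_fc(network: GeneNetwork, fc: FCOverlay) -> GeneNetwork:
    """Attach per-group log2 fold-change-over-mean values to every node."""
    for g in network.graph.nodes:
        if g in fc.log2.index:
            for group in fc.log2.columns:
                network.graph.nodes[g][f"fc_{group}"] = float(fc.log2.loc[g, group])
    return network


@dataclass
class MappingSummary:
    """How one gene set lands on the network: per-cluster membership counts
    and, per condition-group, how many mapped genes are elevated (linear FC
    over mean >= 1)."""

    set_name: str
    present: list[str]
    absent: list[str]
    per_cluster: dict[str, int]
    elevated_per_group: dict[str, int]

    @property
    def n_present(self) -> int:
        return len(self.present)

    def to_row(self) -> dict:
        row = {
            "set": self.set_name,
            "n_present": self.n_present,
            "n_absent": len(self.absent),
            "absent_genes": ",".join(self.absent),
        }
        for cl, n in self.per_cluster.items():
            row[f"n_{cl}"] = n
        for grp, n in self.elevated_per_group.items():
            row[f"n_elevated_{grp}"] = n
        return row


def map_gene_set(
    network: GeneNetwork,
    fc: FCOverlay,
    gene_set: list[str],
    set_name: str = "set",
    flag_nodes: bool = True,
) -> MappingSummary:
    """Map a gene set (pathway members, regulator list, ...) onto the network.

    Reports the "16 of 23 in cluster C1, elevated 12/16 at 4 h"-style summary:
    which members are present, their distribution over clusters, and per group
    how many are elevated (group mean >= grand mean).  An empty intersection
    yields zero counts, not an error.
    """
    nodes = set(network.graph.nodes)
    members = list(dict.fromkeys(gene_set))
    present = sorted(g for g in members if g in nodes)
    absent = sorted(g for g in members if g not in nodes)
    per_cluster: dict[str, int] = {}
    for g in present:
        cl = network.graph.nodes[g].get("cluster", "?")
        per_cluster[cl] = per_cluster.get(cl, 0) + 1
        if flag_nodes:
            network.graph.nodes[g][f"in_{set_name}"] = True
    elevated: dict[str, int] = {}
    for group in fc.log2.columns:
        up = set(fc.elevated(group))
        elevated[group] = sum(1 for g in present if g in up)
    return MappingSummary(set_name, present, absent, dict(sorted(per_cluster.items())), elevated)


@dataclass
class HCResult:
    """Hierarchical-clustering output for the heatmap: deterministic leaf
    orders plus the raw linkage trees."""

    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    zscores: pd.DataFrame

    def cut_genes(self, k: int) -> dict[str, int]:
        """Gene -> flat cluster id when the gene dendrogram is cut into k."""
        labels = hierarchy.fcluster(self.gene_linkage, k, criterion="maxclust")
        genes = list(self.zscores.index)
        return {g: int(l) for g, l in zip(genes, labels)}


def _deterministic_leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    """Leaf order with, at every merge, the subtree containing the smallest
    original index placed first."""
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(linkage):
        la, lb = leaves.pop(int(a)), leaves.pop(int(b))
        if min(lb) < min(la):
            la, lb = lb, la
        leaves[n + k] = la + lb
    (order,) = leaves.values()
    return order


def hierarchical_cluster(log_expr: ExpressionMatrix, genes: list[str]) -> HCResult:
    """Average-linkage clustering of genes (1 - Pearson on z-scored rows) and
    samples (Euclidean on the z-scored matrix).

    Zero-variance genes have no z-score and are dropped with a warning.  Leaf
    orders are deterministic via smallest-original-index-first tie-breaking.
    """
    _require_scale(log_expr, "log2cpm")
    if len(genes) < 2:
        raise ValueError("need at least two genes to cluster")
    sub = log_expr.values.loc[list(genes)]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d zero-variance genes from clustering", int(flat.sum()))
        sub = sub.loc[~flat]
        sd = sd[~flat]
        if sub.shape[0] < 2:
            raise ValueError("fewer than two non-constant genes")
    Z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    X = Z.to_numpy(dtype=float)

    # gene tree: correlation distance 1 - r; rows are z-scored so this is
    # proportional to squared Euclidean distance between rows
    gene_link = hierarchy.linkage(X, method="average", metric="correlation")
    sample_link = hierarchy.linkage(X.T, method="average", metric="euclidean")

    gene_order = [list(Z.index)[i] for i in _deterministic_leaf_order(gene_link, X.shape[0])]
    sample_order = [
        list(Z.columns)[i] for i in _deterministic_leaf_order(sample_link, X.shape[1])
    ]
    return HCResult(gene_order, sample_order, gene_link, sample_link, Z)
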