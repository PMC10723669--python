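"""Per-gene network topology features.

Seven measures summarize each gene's position in the interaction network
relative to a set of known disease genes:

======  ==========================================================
D       degree — number of incident edges
N       number of disease-gene neighbors
R       proportion of neighbors that are disease genes (N/D, 0 if D=0)
B       betweenness centrality, unnormalized unordered-pair counts
C       clustering coefficient — fraction of neighbor pairs adjacent
M       mean shortest-path length (hops) to the disease genes
PR      PageRank mass (damping 0.85); sums to 1 over the network
======  ==========================================================

Guilt-by-association features (N, R, M) are computed against a stated
disease set; a gene is never counted as its own neighbor, and M excludes
the gene itself and unreachable disease genes.  When no disease gene is
reachable, M takes the sentinel value ``n_nodes`` — strictly larger than
any realizable path length, keeping the feature finite and monotone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import PPINetwork, UnknownGeneError

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["D", "N", "R", "B", "C", "M", "PR"]


class PageRankConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, n_iter: int):
        self.residual = residual
        self.n_iter = n_iter
        super().__init__(
            f"PageRank did not converge after {n_iter} iterations "
            f"(last L1 residual {residual:.3e})"
        )


def degree(net: PPINetwork, gene: str) -> int:
    """Number of edges incident to ``gene``."""
    return net.degree(gene)


def disease_neighbor_stats(
    net: PPINetwork, gene: str, disease_set: set[str]
) -> tuple[int, float]:
    """(N, R): disease-gene neighbor count and its proportion of the degree.

    The gene itself is never counted even if it is a disease gene; R is 0
    for isolated genes.
    """
    if not disease_set:
        raise ValueError("disease set is empty")
    nbrs = net.neighbors(gene)
    n = len(nbrs & disease_set - {gene})
    d = len(nbrs)
    return n, (n / d if d > 0 else 0.0)


def betweenness_all(net: PPINetwork) -> dict[str, float]:
    """Unnormalized betweenness: for each node v, the sum over unordered
    pairs {s,t} (s,t != v) of the fraction of shortest s-t paths through v.
    Disconnected pairs contribute 0.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return {
        g: float(b)
        for g, b in nx.betweenness_centrality(net.graph, normalized=False).items()
    }


def clustering_coefficient(net: PPINetwork, gene: str) -> float:
    """Fraction of neighbor pairs that are themselves adjacent; 0 if deg < 2."""
    net._require(gene)
    return float(nx.clustering(net.graph, gene))


def mean_dist_to_disease(
    net: PPINetwork, gene: str, disease_set: set[str]
) -> float:
    """Mean hop count from ``gene`` to each reachable disease gene other than
    itself; sentinel ``n_nodes`` when none is reachable.
    """
    if not disease_set:
        raise ValueError("disease set is empty")
    net._require(gene)
    dist = nx.single_source_shortest_path_length(net.graph, gene)
    lengths = [dist[d] for d in disease_set if d != gene and d in dist]
    if not lengths:
        return float(net.n_nodes)
    return float(np.mean(lengths))


def pagerank_all(
    net: PPINetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Power-iteration PageRank on the undirected graph.

    Each edge acts as two directed links; isolated (dangling) nodes
    redistribute their mass uniformly.  Iteration stops when the L1 change
    between successive vectors drops below ``tol``.

    Raises
    ------
    PageRankConvergenceError
        If ``max_iter`` sweeps do not reach ``tol``.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes = list(net.graph.nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    deg = np.array([net.graph.degree[g] for g in nodes], dtype=float)
    dangling = deg == 0
    # sparse adjacency in CSR for the transition step
    A = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, format="csr", dtype=float)
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        # mass leaving each node, split evenly over its neighbors
        contrib = A.T @ (x * inv_deg)
        dangling_mass = x[dangling].sum()
        x_new = teleport + damping * (contrib + dangling_mass / n)
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            return dict(zip(nodes, map(float, x)))
    raise PageRankConvergenceError(residual, max_iter)


@dataclass
class FeatureTable:
    """Feature rows (one per requested gene, input order) plus provenance.

    ``data`` is indexed by gene with columns ``FEATURE_COLUMNS``; all rows
    were computed against one network and one disease set.
    """

    data: pd.DataFrame
    disease_set_id: str = ""
    network_id: str = ""
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, path, metadata_path=None) -> None:
        out = self.data.rename_axis("gene")
        out.to_csv(path)
        if metadata_path is not None:
            import json

            with open(metadata_path, "w") as fh:
                json.dump(
                    {
                        "network_id": self.network_id,
                        "disease_set_id": self.disease_set_id,
                        "params": self.params,
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="gene")
        return cls(data=df[FEATURE_COLUMNS])


def compute_feature_table(
    net: PPINetwork,
    disease_set: set[str],
    genes: list[str],
    damping: float = 0.85,
    mask_self_label: bool = False,
    network_id: str = "",
    disease_set_id: str = "",
) -> FeatureTable:
    """Compute all seven features for ``genes`` against ``disease_set``.

    Disease-set members absent from the network are dropped with a warning.
    Betweenness and PageRank are computed once network-wide and looked up.
    ``mask_self_label`` removes each evaluated gene from the disease set for
    its own row; under the self-exclusion rules of N and M this is an
    identity, and it is exposed only to make the convention explicit.
    """
    missing = set(g for g in genes if not net.has_node(g))
    if missing:
        raise UnknownGeneError(
            f"requested gene(s) not in network: {sorted(missing)[:5]}"
        )
    absent = disease_set - net.nodes
    if absent:
        warnings.warn(
            f"{len(absent)} disease gene(s) absent from the network were dropped",
            stacklevel=2,
        )
    dset = disease_set & net.nodes
    if not dset:
        raise ValueError("no disease genes present in the network")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes requested")

    btw = betweenness_all(net) if genes else {}
    pr = pagerank_all(net, damping=damping) if genes else {}
    clust = nx.clustering(net.graph, genes) if genes else {}

    # distance-to-disease sums via one BFS per disease gene
    n_nodes = net.n_nodes
    dist_sum: dict[str, float] = {g: 0.0 for g in genes}
    dist_cnt: dict[str, int] = {g: 0 for g in genes}
    gene_set = set(genes)
    for d in dset:
        dist = nx.single_source_shortest_path_length(net.graph, d)
        for g, hops in dist.items():
            if g in gene_set and g != d:
                dist_sum[g] += hops
                dist_cnt[g] += 1

    rows = []
    for g in genes:
        dset_g = dset - {g} if mask_self_label else dset
        nbrs = net.neighbors(g)
        deg_g = len(nbrs)
        n_g = len(nbrs & dset_g - {g})
        cnt = dist_cnt[g]
        m_g = dist_sum[g] / cnt if cnt > 0 else float(n_nodes)
        rows.append(
            {
                "D": deg_g,
                "N": n_g,
                "R": n_g / deg_g if deg_g > 0 else 0.0,
                "B": btw[g],
                "C": float(clust[g]),
                "M": m_g,
                "PR": pr[g],
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=FEATURE_COLUMNS)
    return FeatureTable(
        data=df,
        disease_set_id=disease_set_id,
        network_id=network_id,
        params={"damping": damping, "mask_self_label": mask_self_label},
    )
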