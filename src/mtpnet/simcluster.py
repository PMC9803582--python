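"""SimCluster: hub-miRNA discovery from similarity networks.

The algorithm runs in three steps over a miRNA–target–pathway network:

1. **Similarity.** Pairwise Jaccard similarity of miRNAs — first order on
   their target sets, second order on their (two-hop) pathway sets.
2. **Scale-free thresholding.** For a grid of candidate thresholds, build
   the graph keeping edges with similarity >= tau, drop isolated nodes, and
   test scale-freeness: the Pearson correlation and OLS R^2 between
   lg(K) (log10 degree) and lg(pK) (log10 degree frequency) must both
   exceed 0.9 with a negative slope. The smallest qualifying tau is chosen.
3. **Clustering and hubs.** Partition the thresholded graph with several
   modularity-based community algorithms, keep the partition with the
   highest Newman–Girvan modularity Q, and from each module take every node
   attaining the maximum (graph-wide) degree among the module's members —
   ties are all included.

Finally the SimCluster hubs are intersected with WGCNA hubs: the combined
hub set carries both correlation (co-expression) and similarity
(shared-mechanism) evidence.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.stats import linregress, pearsonr

from .mtp_core import MTPNetwork, pathway_sets, target_sets

logger = logging.getLogger("mtpnet")

DEFAULT_GRID = [round(0.05 * i, 2) for i in range(1, 20)]  # 0.05 .. 0.95
DEFAULT_ALGORITHMS = (
    "fast_greedy",
    "louvain",
    "label_propagation",
    "leading_eigenvector",
)


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets return 0 by convention."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class SimilarityNetwork:
    """Symmetric miRNA similarity matrix, optionally thresholded to a graph."""

    order: int  # 1 = target-set level, 2 = pathway-set level
    ids: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    tau: float | None = None
    graph: nx.Graph | None = None
    excluded: list[str] = field(default_factory=list)
    scan: list["ScaleFreeFit"] = field(default_factory=list)


def similarity_matrix(net: MTPNetwork, order: int = 1) -> SimilarityNetwork:
    """Pairwise Jaccard similarity of miRNAs at the target (order 1) or
    pathway (order 2) level, computed via binary membership matrices."""
    if order == 1:
        sets = target_sets(net)
    elif order == 2:
        sets = pathway_sets(net)
    else:
        raise ValueError("order must be 1 or 2")
    ids = sorted(sets)
    if not ids:
        raise ValueError("network has no miRNA nodes")
    universe = sorted(set().union(*sets.values())) if sets else []
    uindex = {u: j for j, u in enumerate(universe)}
    member = np.zeros((len(ids), max(len(universe), 1)), dtype=float)
    for i, m in enumerate(ids):
        for u in sets[m]:
            member[i, uindex[u]] = 1.0
    inter = member @ member.T
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityNetwork(order=order, ids=ids, matrix=sim)


def threshold_graph(
    sim: SimilarityNetwork, tau: float, strict_gt: bool = False
) -> tuple[nx.Graph, list[str]]:
    """Graph keeping edges with similarity >= tau (or > tau when
    ``strict_gt``); degree-0 nodes are dropped and returned separately."""
    n = len(sim.ids)
    g = nx.Graph()
    mat = sim.matrix
    for i in range(n):
        for j in range(i + 1, n):
            keep = mat[i, j] > tau if strict_gt else mat[i, j] >= tau
            if keep:
                g.add_edge(sim.ids[i], sim.ids[j], weight=float(mat[i, j]))
    excluded = [m for m in sim.ids if m not in g]
    return g, excluded


@dataclass
class ScaleFreeFit:
    """Log–log degree-distribution fit of a thresholded similarity graph."""

    tau: float
    degrees: np.ndarray  # distinct degree values K (>= 1)
    frequencies: np.ndarray  # pK = fraction of nodes at each K
    cor: float
    r2: float
    slope: float
    n_nodes: int
    reliable: bool

    @property
    def qualifies(self) -> bool:
        return self.reliable and self.slope < 0


def scale_free_fit(graph: nx.Graph, tau: float = float("nan")) -> ScaleFreeFit:
    """Pearson correlation and OLS R^2 between lg(K) and lg(pK).

    Fits with fewer than 3 distinct degree values are flagged unreliable
    (a 2-point regression is always exact) and never qualify.
    """
    degs = np.array([d for _, d in graph.degree()], dtype=int)
    degs = degs[degs >= 1]
    n_nodes = graph.number_of_nodes()
    if degs.size == 0 or n_nodes == 0:
        return ScaleFreeFit(tau, np.array([]), np.array([]), 0.0, 0.0, 0.0, 0, False)
    ks, counts = np.unique(degs, return_counts=True)
    pk = counts / n_nodes
    if ks.size < 3:
        return ScaleFreeFit(tau, ks, pk, 0.0, 0.0, 0.0, n_nodes, False)
    x, y = np.log10(ks), np.log10(pk)
    cor = float(pearsonr(x, y).statistic)
    fit = linregress(x, y)
    return ScaleFreeFit(
        tau=tau,
        degrees=ks,
        frequencies=pk,
        cor=cor,
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        n_nodes=n_nodes,
        reliable=True,
    )


def select_threshold(
    sim: SimilarityNetwork,
    grid: list[float] | None = None,
    cor_min: float = 0.9,
    r2_min: float = 0.9,
    strict_gt: bool = False,
    on_fail: str = "raise",
) -> SimilarityNetwork:
    """Choose the smallest tau whose thresholded graph is scale-free.

    A tau qualifies when |Cor| >= cor_min, R^2 >= r2_min and the regression
    slope is negative (degree frequencies decay). The full scan is recorded
    on the returned network. If no tau qualifies, the default is to raise a
    ValueError reporting the best-scoring row; ``on_fail="best"`` instead
    keeps that row (largest min(|Cor|, R^2) among reliable negative-slope
    fits) with a warning — useful when the similarity network is genuinely
    not scale-free but downstream clustering should still proceed.
    """
    if on_fail not in ("raise", "best"):
        raise ValueError("on_fail must be 'raise' or 'best'")
    grid = sorted(grid) if grid is not None else list(DEFAULT_GRID)
    scan: list[ScaleFreeFit] = []
    chosen: float | None = None
    chosen_graph: nx.Graph | None = None
    chosen_excluded: list[str] = []
    for tau in grid:
        g, excluded = threshold_graph(sim, tau, strict_gt=strict_gt)
        fit = scale_free_fit(g, tau=tau)
        scan.append(fit)
        if (
            chosen is None
            and fit.qualifies
            and abs(fit.cor) >= cor_min
            and fit.r2 >= r2_min
        ):
            chosen, chosen_graph, chosen_excluded = tau, g, excluded
    if chosen is None:
        best = max(
            (f for f in scan if f.qualifies),
            key=lambda f: min(abs(f.cor), f.r2),
            default=None,
        )
        detail = (
            f"best row: tau={best.tau} |Cor|={abs(best.cor):.3f} R2={best.r2:.3f}"
            if best
            else "no reliable decaying fit on the grid"
        )
        if on_fail == "raise" or best is None:
            raise ValueError(
                f"no threshold satisfies the scale-free criterion ({detail})"
            )
        logger.warning("scale-free criterion unmet; falling back to %s", detail)
        chosen = best.tau
        chosen_graph, chosen_excluded = threshold_graph(
            sim, chosen, strict_gt=strict_gt
        )
    out = SimilarityNetwork(
        order=sim.order,
        ids=sim.ids,
        matrix=sim.matrix,
        tau=chosen,
        graph=chosen_graph,
        excluded=chosen_excluded,
        scan=scan,
    )
    logger.info(
        "selected similarity threshold tau=%.3f (%d nodes, %d edges kept)",
        chosen,
        chosen_graph.number_of_nodes(),
        chosen_graph.number_of_edges(),
    )
    return out


# -- clustering ------------------------------------------------------------


@dataclass
class ClusterResult:
    algorithm: str
    membership: dict[str, int]
    modularity: float

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mod in self.membership.items():
            out.setdefault(mod, []).append(node)
        return out


def newman_girvan_modularity(graph: nx.Graph, membership: dict[str, int]) -> float:
    """Q = sum over communities of (e_c / m - (d_c / 2m)^2), unweighted."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    e: dict[int, int] = {}
    d: dict[int, int] = {}
    for u, v in graph.edges():
        cu, cv = membership[u], membership[v]
        if cu == cv:
            e[cu] = e.get(cu, 0) + 1
    for node, deg in graph.degree():
        c = membership[node]
        d[c] = d.get(c, 0) + deg
    return float(
        sum(e.get(c, 0) / m - (d.get(c, 0) / (2 * m)) ** 2 for c in set(d))
    )


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def cluster_graph(
    graph: nx.Graph,
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    seed: int = 0,
) -> tuple[ClusterResult, list[ClusterResult]]:
    """Run several community-detection algorithms; keep the highest-Q one.

    Q is recomputed from the Newman–Girvan definition rather than taken
    from the clustering backend; ties go to the earlier algorithm in the
    list. Known algorithms: fast_greedy, louvain, label_propagation,
    leading_eigenvector.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    g, nodes = _to_igraph(graph)
    results: list[ClusterResult] = []
    for name in algorithms:
        random.seed(seed)  # igraph's stochastic methods use Python's RNG
        try:
            if name == "fast_greedy":
                comm = g.community_fastgreedy().as_clustering()
            elif name == "louvain":
                comm = g.community_multilevel()
            elif name == "label_propagation":
                comm = g.community_label_propagation()
            elif name == "leading_eigenvector":
                comm = g.community_leading_eigenvector()
            else:
                raise ValueError(f"unknown clustering algorithm {name!r}")
        except ValueError:
            raise
        except Exception as exc:  # e.g. ARPACK non-convergence
            logger.warning("clustering algorithm %s failed (%s); skipped", name, exc)
            continue
        membership = {nodes[i]: int(c) for i, c in enumerate(comm.membership)}
        q = newman_girvan_modularity(graph, membership)
        results.append(ClusterResult(algorithm=name, membership=membership, modularity=q))
    if not results:
        raise RuntimeError("every clustering algorithm failed")
    best = max(results, key=lambda r: r.modularity)  # max keeps first on ties
    return best, results


def module_hubs(result: ClusterResult, graph: nx.Graph) -> set[str]:
    """Per module, every node attaining the maximum graph-wide degree among
    the module's members (ties all included); union over modules."""
    hubs: set[str] = set()
    deg = dict(graph.degree())
    for members in result.modules().values():
        if not members:
            continue
        top = max(deg[n] for n in members)
        hubs.update(n for n in members if deg[n] == top)
    return hubs


def intersect_hubs(wgcna_hubs: set[str], simcluster_hubs: set[str]) -> set[str]:
    """Hubs supported by both correlation and similarity evidence."""
    inter = set(wgcna_hubs) & set(simcluster_hubs)
    if not inter:
        logger.warning("WGCNA and SimCluster hub sets are disjoint")
    return inter
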