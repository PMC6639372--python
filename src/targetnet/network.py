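"""Interaction-network loading and graph-derived gene descriptors.

Covers three families of per-gene features used by the drug-target
predictor:

* node centralities (degree, betweenness, closeness; optionally PageRank,
  eigenvector, Katz, and in-/out-degree on directed networks),
* shortest-path distance summaries from a gene to each of the seven node
  types (six gene classes plus the OG background),
* the composition of a gene's direct neighborhood in terms of those seven
  node types.

Distances to unreachable or empty target sets are encoded by a finite
sentinel, by default the number of nodes in the graph, which exceeds any
realizable shortest-path length and keeps "farther" monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import NODE_TYPES, GeneClassCatalog, node_type_sets, normalize_symbol

UNDIRECTED_MEASURES = ("degree", "betweenness", "closeness", "pagerank", "eigenvector", "katz")
DIRECTED_ONLY_MEASURES = ("in_degree", "out_degree")


@dataclass
class InteractionNetwork:
    """Thin wrapper around a networkx graph of gene symbols.

    Self-loops are removed on construction; undirected duplicate edges
    collapse naturally in the underlying ``nx.Graph``.  ``edge_sign``
    (``positive`` / ``negative`` / ``physical``) is kept as an edge
    attribute when present but does not affect any computation here.
    """

    graph: nx.Graph | nx.DiGraph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        """Adjacent nodes; union of in- and out-neighbors when directed."""
        if self.directed:
            return set(self.graph.successors(node)) | set(self.graph.predecessors(node))
        return set(self.graph.neighbors(node))

    @property
    def default_sentinel(self) -> int:
        return self.n_nodes


def from_edges(
    edges: Iterable[tuple[str, str]], directed: bool = False
) -> InteractionNetwork:
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(g)


def load_network(
    path: str | Path,
    directed: bool = False,
    sign_column: int | None = None,
    column_map: Mapping[str, int] | None = None,
    skip_header: bool = False,
) -> InteractionNetwork:
    """Load an interaction network from a TSV edge list.

    The plain dialect has columns ``source<TAB>target[<TAB>sign]``.  For
    BioGRID tab3-style exports pass ``column_map`` with keys ``source``
    and ``target`` giving 0-based column indices of the official-symbol
    columns (tab3: 7 and 8) and ``skip_header=True``.
    """
    path = Path(path)
    src_col = column_map["source"] if column_map else 0
    tgt_col = column_map["target"] if column_map else 1
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max(src_col, tgt_col):
                raise ValueError(
                    f"{path}:{lineno}: expected at least "
                    f"{max(src_col, tgt_col) + 1} columns, got {len(fields)}"
                )
            u = normalize_symbol(fields[src_col])
            v = normalize_symbol(fields[tgt_col])
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            attrs = {}
            if sign_column is not None and len(fields) > sign_column:
                attrs["sign"] = fields[sign_column].strip()
            g.add_edge(u, v, **attrs)
    net = InteractionNetwork(g)
    if net.n_nodes == 0:
        raise ValueError(f"{path}: network is empty after loading")
    return net


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(net.graph.edges(data=True)):
            sign = data.get("sign")
            fh.write(f"{u}\t{v}\t{sign}\n" if sign else f"{u}\t{v}\n")


def centralities(
    net: InteractionNetwork,
    measures: Sequence[str] = ("degree", "betweenness", "closeness"),
) -> pd.DataFrame:
    """Per-node centralities, one column per requested measure.

    Degree is normalized by ``n - 1``; betweenness is normalized;
    closeness uses the Wasserman-Faust correction so nodes are scored on
    their reachable set even in a disconnected graph.  Katz attenuation
    defaults to ``0.9 / lambda_max``.
    """
    valid = UNDIRECTED_MEASURES + DIRECTED_ONLY_MEASURES
    for m in measures:
        if m not in valid:
            raise ValueError(f"unknown centrality measure {m!r}")
        if m in DIRECTED_ONLY_MEASURES and not net.directed:
            raise ValueError(f"{m} centrality requires a directed network")
    g = net.graph
    cols: dict[str, dict] = {}
    for m in measures:
        if m == "degree":
            cols[m] = nx.degree_centrality(g)
        elif m == "in_degree":
            cols[m] = nx.in_degree_centrality(g)
        elif m == "out_degree":
            cols[m] = nx.out_degree_centrality(g)
        elif m == "betweenness":
            cols[m] = nx.betweenness_centrality(g, normalized=True)
        elif m == "closeness":
            cols[m] = nx.closeness_centrality(g, wf_improved=True)
        elif m == "pagerank":
            cols[m] = nx.pagerank(g)
        elif m == "eigenvector":
            try:
                cols[m] = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-8)
            except nx.PowerIterationFailedConvergence as exc:
                raise RuntimeError(
                    "eigenvector centrality failed to converge; "
                    "consider Katz centrality instead"
                ) from exc
        elif m == "katz":
            lam = _spectral_radius(g)
            alpha = 0.9 / lam if lam > 0 else 0.1
            cols[m] = nx.katz_centrality(g, alpha=alpha, max_iter=5000, tol=1e-8)
    nodes = list(g.nodes)
    return pd.DataFrame({m: [cols[m][n] for n in nodes] for m in measures},
                        index=pd.Index(nodes, name="gene"))


def _spectral_radius(g: nx.Graph | nx.DiGraph) -> float:
    a = nx.to_numpy_array(g)
    return float(np.max(np.abs(np.linalg.eigvals(a))).real)


def class_distance_summary(
    net: InteractionNetwork,
    node: str,
    target_set: set[str],
    exclude_self: bool = True,
    sentinel: int | None = None,
) -> tuple[float, float]:
    """Average and minimum shortest-path length from ``node`` to a gene set.

    Directed networks follow outgoing edges (paths *from* the node).
    When the effective target set is empty or entirely unreachable both
    summaries equal the sentinel.
    """
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    if sentinel is None:
        sentinel = net.default_sentinel
    targets = set(target_set)
    if exclude_self:
        targets.discard(node)
    if not targets:
        return float(sentinel), float(sentinel)
    dist = nx.single_source_shortest_path_length(net.graph, node)
    found = [dist[t] for t in targets if t in dist]
    if not found:
        return float(sentinel), float(sentinel)
    return float(np.mean(found)), float(min(found))


def all_class_distances(
    net: InteractionNetwork,
    catalog: GeneClassCatalog,
    exclude_self: bool = True,
    sentinel: int | None = None,
) -> pd.DataFrame:
    """Distance summaries from every node to all seven node types.

    Equivalent to calling :func:`class_distance_summary` for every
    (node, node type) pair but computed with one BFS per *target* gene:
    distances from target ``t`` are accumulated into running sums,
    counts and minima over all source nodes.  On directed graphs the BFS
    runs on the reversed graph so accumulated distances are source->target.

    Columns are ``dist_<TYPE>_avg`` and ``dist_<TYPE>_min`` for TYPE in
    DTG, DAG, PFG, PUG, URG, DRG, OG.
    """
    if sentinel is None:
        sentinel = net.default_sentinel
    sets = node_type_sets(catalog, net)
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    bfs_graph = net.graph.reverse(copy=False) if net.directed else net.graph
    out: dict[str, np.ndarray] = {}
    for label in NODE_TYPES:
        members = sets[label]
        sums = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        mins = np.full(n, np.inf)
        for t in members:
            dist = nx.single_source_shortest_path_length(bfs_graph, t)
            for src, d in dist.items():
                i = index[src]
                if exclude_self and src == t:
                    continue
                sums[i] += d
                counts[i] += 1
                if d < mins[i]:
                    mins[i] = d
        avg = np.full(n, float(sentinel))
        reached = counts > 0
        avg[reached] = sums[reached] / counts[reached]
        mins[~np.isfinite(mins)] = float(sentinel)
        out[f"dist_{label}_avg"] = avg
        out[f"dist_{label}_min"] = mins
    return pd.DataFrame(out, index=pd.Index(nodes, name="gene"))


def neighbor_class_ratios(
    net: InteractionNetwork, node: str, catalog: GeneClassCatalog
) -> dict[str, float]:
    """Fraction of a node's neighbors belonging to each of the 7 node types.

    A neighbor with several labels counts toward each of them, so the
    ratios can sum above 1.  Isolated nodes get all-zero ratios.
    """
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    sets = node_type_sets(catalog, net)
    nbrs = net.neighbors(node)
    if not nbrs:
        return {label: 0.0 for label in NODE_TYPES}
    k = len(nbrs)
    return {label: len(nbrs & sets[label]) / k for label in NODE_TYPES}


def all_neighbor_ratios(
    net: InteractionNetwork, catalog: GeneClassCatalog
) -> pd.DataFrame:
    """Neighbor-type ratios for every node (columns ``ratio_<TYPE>``)."""
    sets = node_type_sets(catalog, net)
    nodes = list(net.nodes)
    rows = np.zeros((len(nodes), len(NODE_TYPES)))
    for i, node in enumerate(nodes):
        nbrs = net.neighbors(node)
        if not nbrs:
            continue
        k = len(nbrs)
        for j, label in enumerate(NODE_TYPES):
            rows[i, j] = len(nbrs & sets[label]) / k
    return pd.DataFrame(
        rows,
        index=pd.Index(nodes, name="gene"),
        columns=[f"ratio_{label}" for label in NODE_TYPES],
    )


@dataclass
class GroupDistanceResult:
    """Distance comparison of one gene class against another vs. the OG
    background, from the perspective of ``class_a`` nodes."""

    class_a: str
    class_b: str
    per_node: pd.DataFrame = field(repr=False)
    statistic_avg: float = np.nan
    p_value_avg: float = np.nan
    statistic_min: float = np.nan
    p_value_min: float = np.nan
    direction: str = "none"  # closer | farther | none, relative to OG


def group_distance_analysis(
    net: InteractionNetwork,
    catalog: GeneClassCatalog,
    class_a: str,
    class_b: str,
    sentinel: int | None = None,
) -> GroupDistanceResult:
    """Are ``class_a`` genes closer to ``class_b`` genes than to background?

    For each node of ``class_a`` the average and minimum shortest-path
    length to ``class_b`` members and to OG nodes is computed (self
    excluded where applicable); the two per-node distributions are
    compared with a two-sided Wilcoxon rank-sum test.
    """
    sets = node_type_sets(catalog, net)
    a_nodes = sorted(sets[class_a]) if class_a != "OG" else sorted(sets["OG"])
    b_set = sets[class_b]
    og_set = sets["OG"]
    if not a_nodes or not b_set:
        raise ValueError(f"class {class_a if not a_nodes else class_b} empty after restriction")
    records = []
    for node in a_nodes:
        avg_b, min_b = class_distance_summary(net, node, b_set, sentinel=sentinel)
        avg_og, min_og = class_distance_summary(net, node, og_set, sentinel=sentinel)
        records.append((node, avg_b, min_b, avg_og, min_og))
    per_node = pd.DataFrame(
        records, columns=["gene", "avg_to_class", "min_to_class", "avg_to_og", "min_to_og"]
    ).set_index("gene")
    res_avg = stats.mannwhitneyu(
        per_node.avg_to_class, per_node.avg_to_og, alternative="two-sided"
    )
    res_min = stats.mannwhitneyu(
        per_node.min_to_class, per_node.min_to_og, alternative="two-sided"
    )
    med_b = per_node.avg_to_class.median()
    med_og = per_node.avg_to_og.median()
    direction = "closer" if med_b < med_og else ("farther" if med_b > med_og else "none")
    return GroupDistanceResult(
        class_a=class_a,
        class_b=class_b,
        per_node=per_node,
        statistic_avg=float(res_avg.statistic),
        p_value_avg=float(res_avg.pvalue),
        statistic_min=float(res_min.statistic),
        p_value_min=float(res_min.pvalue),
        direction=direction,
    )
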