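"""Node centrality indices on the rewired network, Cytoscape conventions.

All rewired edge classes are treated as undirected, unweighted edges.
Reported per node: degree, betweenness centrality (Brandes, normalized
by (n-1)(n-2)/2), closeness centrality (reciprocal of the mean
shortest-path distance within the node's component), local clustering
coefficient, and neighborhood connectivity (mean degree of neighbors).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .cooccurrence import DifferentialNetwork


def to_graph(dnet: DifferentialNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(dnet.nodes)
    for a, b, cls in zip(dnet.edges["taxon_a"], dnet.edges["taxon_b"],
                         dnet.edges["class"]):
        g.add_edge(a, b, rewiring=cls)
    return g


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Normalized Brandes betweenness; components handled naturally."""
    return nx.betweenness_centrality(g, normalized=True)


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Component-local closeness: (|R(v)|) / sum of distances to R(v).

    R(v) is the set of nodes reachable from v (excluding v itself);
    isolated nodes get 0.  This matches the convention Cytoscape uses
    for disconnected graphs.
    """
    return nx.closeness_centrality(g, wf_improved=False)


def local_clustering(g: nx.Graph) -> dict[str, float]:
    """Fraction of closed triangles among each node's neighbor pairs."""
    return nx.clustering(g)


def neighborhood_connectivity(g: nx.Graph) -> dict[str, float]:
    """Mean degree over each node's neighbors (0 for isolated nodes)."""
    deg = dict(g.degree())
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        out[v] = sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def centrality_table(dnet: DifferentialNetwork | nx.Graph) -> pd.DataFrame:
    """All five node indices on the rewired graph, sorted by degree.

    Columns: degree, betweenness, closeness, clustering,
    neighborhood_connectivity; rows sorted by degree descending then
    node name.
    """
    g = dnet if isinstance(dnet, nx.Graph) else to_graph(dnet)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities on an empty network")
    deg = dict(g.degree())
    btw = betweenness_centrality(g)
    clo = closeness_centrality(g)
    clu = local_clustering(g)
    nbc = neighborhood_connectivity(g)
    out = pd.DataFrame({
        "degree": pd.Series(deg),
        "betweenness": pd.Series(btw),
        "closeness": pd.Series(clo),
        "clustering": pd.Series(clu),
        "neighborhood_connectivity": pd.Series(nbc),
    }).rename_axis("node")
    out = out.sort_values(["degree", "node"], ascending=[False, True],
                          kind="stable")
    return out
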