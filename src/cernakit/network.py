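"""ceRNA network assembly, centralities, hub selection, sub-network extraction.

The ceRNA hypothesis: circRNAs sequester shared miRNAs and thereby
de-repress the miRNAs' target genes, so a circRNA acting through a miRNA
should move in the *same* direction as the gene it sponges for.  The
builder therefore joins circRNA-miRNA and miRNA-gene tables on shared
miRNAs and prunes every circ-miR-gene path whose circRNA and gene
directions disagree (miRNA expression itself plays no role: it is not
measured).
"""

from __future__ import annotations

import numbers

import networkx as nx
import pandas as pd

from cernakit.containers import (
    CONFIDENCE_CLASSES,
    CeRNANetwork,
    validate_interaction_table,
)


def filter_by_confidence(table: pd.DataFrame, cutoff) -> pd.DataFrame:
    """Keep rows at/above a confidence class, or strictly above a score.

    Ordered classes use ``confidence >= cutoff``; numeric scores use the
    strict ``confidence > cutoff`` convention of combined-score PPI
    filters.  Row order is preserved.
    """
    if table.empty:
        return table.copy()
    conf = table["confidence"]
    is_num = conf.map(lambda v: isinstance(v, numbers.Number) and not isinstance(v, bool))
    if isinstance(cutoff, str):
        if is_num.any():
            raise ValueError("class cutoff applied to a numeric confidence column")
        if cutoff not in CONFIDENCE_CLASSES:
            raise ValueError(f"unknown confidence class {cutoff!r}")
        rank = {c: i for i, c in enumerate(CONFIDENCE_CLASSES)}
        bad = set(conf) - set(CONFIDENCE_CLASSES)
        if bad:
            raise ValueError(f"unknown confidence classes in table: {sorted(bad)}")
        keep = conf.map(rank) >= rank[cutoff]
    else:
        if not is_num.all():
            raise ValueError("score cutoff applied to a non-numeric confidence column")
        keep = conf > cutoff
    return table[keep].copy()


def build_cerna_network(
    circ_mir: pd.DataFrame,
    mir_gene: pd.DataFrame,
    circ_directions: dict[str, str],
    gene_directions: dict[str, str],
) -> CeRNANetwork:
    """Join the two tables on shared miRNAs and apply the direction filter.

    Keeps a circ-miR edge iff some gene of that miRNA shares the circRNA's
    direction, and a miR-gene edge iff some circRNA of that miRNA shares
    the gene's direction (maximal retention: an edge survives any one
    consistent partner).  Nodes left without edges are dropped.
    """
    validate_interaction_table(circ_mir)
    validate_interaction_table(mir_gene)
    cm = circ_mir[["source", "target"]].drop_duplicates()
    mg = mir_gene[["source", "target"]].drop_duplicates()

    shared = set(cm["target"]) & set(mg["source"])
    cm = cm[cm["target"].isin(shared)]
    mg = mg[mg["source"].isin(shared)]

    for node in cm["source"]:
        if node not in circ_directions:
            raise ValueError(f"unknown direction for circRNA {node!r}")
    for node in mg["target"]:
        if node not in gene_directions:
            raise ValueError(f"unknown direction for gene {node!r}")

    circ_dirs_by_mir: dict[str, set[str]] = {}
    gene_dirs_by_mir: dict[str, set[str]] = {}
    for _, row in cm.iterrows():
        circ_dirs_by_mir.setdefault(row["target"], set()).add(
            circ_directions[row["source"]]
        )
    for _, row in mg.iterrows():
        gene_dirs_by_mir.setdefault(row["source"], set()).add(
            gene_directions[row["target"]]
        )

    graph = nx.Graph()
    for _, row in cm.iterrows():
        c, m = row["source"], row["target"]
        if circ_directions[c] in gene_dirs_by_mir.get(m, set()):
            graph.add_node(c, role="circ", direction=circ_directions[c])
            graph.add_node(m, role="mir")
            graph.add_edge(c, m, edge_type="circ-mir")
    for _, row in mg.iterrows():
        m, g = row["source"], row["target"]
        if gene_directions[g] in circ_dirs_by_mir.get(m, set()):
            graph.add_node(m, role="mir")
            graph.add_node(g, role="gene", direction=gene_directions[g])
            graph.add_edge(m, g, edge_type="mir-gene")
    graph.remove_nodes_from([n for n in graph if graph.degree(n) == 0])
    return CeRNANetwork(graph)


def _as_graph(edges: pd.DataFrame | nx.Graph) -> nx.Graph:
    if isinstance(edges, nx.Graph):
        return edges
    validate_interaction_table(edges)
    g = nx.Graph()
    g.add_edges_from(zip(edges["source"], edges["target"]))
    return g


def degree_centrality(edges: pd.DataFrame | nx.Graph) -> dict[str, int]:
    """Per-node edge count in the simple undirected graph."""
    return dict(_as_graph(edges).degree())


def closeness_centrality(edges: pd.DataFrame | nx.Graph) -> dict[str, float]:
    """(n_c - 1) / sum of shortest-path distances within the node's
    connected component; isolated nodes get 0."""
    return nx.closeness_centrality(_as_graph(edges), wf_improved=False)


def betweenness_centrality(edges: pd.DataFrame | nx.Graph) -> dict[str, float]:
    """Unnormalised shortest-path betweenness (each unordered pair of
    endpoints counted once), via Brandes' accumulation."""
    return nx.betweenness_centrality(_as_graph(edges), normalized=False)


def centrality_table(edges: pd.DataFrame | nx.Graph) -> pd.DataFrame:
    g = _as_graph(edges)
    deg = degree_centrality(g)
    clo = closeness_centrality(g)
    bet = betweenness_centrality(g)
    return (
        pd.DataFrame(
            {
                "id": list(g.nodes),
                "degree": [deg[n] for n in g.nodes],
                "closeness": [clo[n] for n in g.nodes],
                "betweenness": [bet[n] for n in g.nodes],
            }
        )
        .sort_values("id")
        .reset_index(drop=True)
    )


def select_hub_genes(ppi: pd.DataFrame | nx.Graph) -> pd.DataFrame:
    """Genes strictly above the network mean on betweenness, closeness AND
    degree, sorted by degree then betweenness descending.

    Isolated nodes never appear in an edge list and so are excluded from
    the averages by construction.
    """
    table = centrality_table(ppi)
    if table.empty:
        return table.assign(is_hub=pd.Series(dtype=bool))
    means = table[["degree", "closeness", "betweenness"]].mean()
    table["is_hub"] = (
        (table["degree"] > means["degree"])
        & (table["closeness"] > means["closeness"])
        & (table["betweenness"] > means["betweenness"])
    )
    hubs = (
        table[table["is_hub"]]
        .sort_values(["degree", "betweenness"], ascending=False)
        .reset_index(drop=True)
    )
    return hubs


def extract_subnetwork(net: CeRNANetwork, hubs: list[str]) -> CeRNANetwork:
    """Induced sub-network on hub genes, the miRNAs adjacent to them, and
    the circRNAs adjacent to those miRNAs."""
    gene_nodes = set(net.genes)
    missing = [h for h in hubs if h not in gene_nodes]
    if missing:
        raise ValueError(f"hub genes absent from the network: {missing}")
    g = net.graph
    keep_genes = set(hubs)
    keep_mirs = {
        m
        for gene in keep_genes
        for m in g.neighbors(gene)
        if g.nodes[m]["role"] == "mir"
    }
    keep_circs = {
        c
        for m in keep_mirs
        for c in g.neighbors(m)
        if g.nodes[c]["role"] == "circ"
    }
    sub = nx.Graph()
    keep = keep_genes | keep_mirs | keep_circs
    for n in keep:
        sub.add_node(n, **g.nodes[n])
    for u, v, data in g.edges(data=True):
        if u in keep and v in keep:
            sub.add_edge(u, v, **data)
    sub.remove_nodes_from([n for n in sub if sub.degree(n) == 0])
    return CeRNANetwork(sub)


def write_sif(net: CeRNANetwork, path) -> None:
    """Simple interaction format: node <TAB> edge_type <TAB> node."""
    edges = net.edge_table()
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['source']}\t{row['edge_type']}\t{row['target']}\n")


def write_node_attributes(net: CeRNANetwork, path, centralities: pd.DataFrame | None = None) -> None:
    nodes = net.node_table()
    if centralities is not None:
        nodes = nodes.merge(centralities, on="id", how="left")
    nodes.to_csv(path, sep="\t", index=False)


def write_graphml(net: CeRNANetwork, path) -> None:
    nx.write_graphml(net.graph, path)
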