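"""Local Gene Network (LGN) assembly and decomposition.

The LGN is a knowledge-based typed graph anchored on disease-associated
differentially expressed genes: gene nodes (attribute ``regulation`` ∈
{up, down, none}) and pathway nodes (id + display name) joined by
``membership`` edges, with ``pathway_link`` edges between pathway nodes
either supplied explicitly (reconstructing printed sub-structures) or
derived from shared membership.  A pathway enters the network iff it
contains at least one disease-associated DE gene; optionally the other
disease-set genes of those pathways join with ``regulation = "none"``.

All edges are undirected; gene symbols match case-insensitively while the
first-seen spelling is preserved on the node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import networkx as nx
import pandas as pd

from .errors import InputError
from .io import DiseaseGeneSet, PathwayCollection, norm_symbol

logger = logging.getLogger("starchnet")

__all__ = [
    "ComponentDecomposition",
    "map_disease_genes",
    "build_lgn",
    "decompose",
    "project",
]


def map_disease_genes(degs: pd.DataFrame, disease: DiseaseGeneSet) -> pd.DataFrame:
    """Subtable of screened genes (call up/down) present in the disease set.

    Matching is case-insensitive; ratio and call are retained.  An empty
    intersection is legitimate (logged, not raised).
    """
    called = degs[degs["call"].isin(["up", "down"])]
    keep = [g for g in called.index if g in disease]
    sub = called.loc[keep]
    if sub.empty:
        logger.warning("no differentially expressed gene maps into the disease set")
    return sub


def build_lgn(disease_degs: pd.DataFrame, pathways: PathwayCollection,
              include_neighbor_genes: bool = False,
              disease: DiseaseGeneSet | None = None,
              links: list[tuple[str, str]] | None = None) -> nx.Graph:
    """Assemble the LGN from disease-associated DEGs and pathway annotations.

    Parameters
    ----------
    disease_degs
        Output of :func:`map_disease_genes` (index = gene symbol, must carry
        a ``call`` column).
    pathways
        The pathway knowledge base; a pathway is included iff it contains at
        least one of the ``disease_degs``.
    include_neighbor_genes
        Also attach the other disease-set genes participating in the
        included pathways, with ``regulation = "none"`` (requires
        ``disease``).
    links
        Explicit pathway–pathway link edges; overrides the default
        shared-membership derivation.  Referencing a pathway absent from the
        assembled graph is an error.
    """
    if include_neighbor_genes and disease is None:
        raise InputError("include_neighbor_genes requires the disease gene set")

    reg_of = {norm_symbol(g): (g, disease_degs.loc[g, "call"])
              for g in disease_degs.index}

    g = nx.Graph()
    included: list[str] = []
    for pid, name, members in pathways:
        hit = [m for m in members if norm_symbol(m) in reg_of]
        if not hit:
            continue
        included.append(pid)
        g.add_node(pid, node_type="pathway", name=name, regulation="none")
        for m in members:
            key = norm_symbol(m)
            if key in reg_of:
                sym, call = reg_of[key]
                g.add_node(sym, node_type="gene", regulation=call)
                g.add_edge(sym, pid, edge_type="membership")
            elif include_neighbor_genes and m in disease:
                g.add_node(m, node_type="gene", regulation="none")
                g.add_edge(m, pid, edge_type="membership")

    if links is not None:
        present = set(included)
        for a, b in links:
            for p in (a, b):
                if p not in present:
                    raise InputError(f"pathway link references absent pathway id {p!r}")
            if a != b:
                g.add_edge(a, b, edge_type="pathway_link")
    else:
        member_keys = {
            pid: {norm_symbol(m) for m in pathways.members(pid)} for pid in included}
        for i, a in enumerate(included):
            for b in included[i + 1:]:
                if member_keys[a] & member_keys[b]:
                    g.add_edge(a, b, edge_type="pathway_link")
    return g


@dataclass
class ComponentDecomposition:
    """Connected components ordered by decreasing size; ties broken by the
    smallest lexicographically-minimal node id."""

    components: list[set[str]] = field(default_factory=list)
    main: set[str] = field(default_factory=set)
    isolated_pathways: list[str] = field(default_factory=list)


def decompose(graph: nx.Graph) -> ComponentDecomposition:
    """Undirected connected components over both edge types.

    ``main`` is the largest component; pathway nodes outside it are the
    isolated pathways.
    """
    if graph.number_of_nodes() == 0:
        return ComponentDecomposition()
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(str(x) for x in c)))
    main = comps[0]
    isolated = sorted(
        n for n, d in graph.nodes(data=True)
        if d.get("node_type") == "pathway" and n not in main)
    return ComponentDecomposition(components=comps, main=main,
                                  isolated_pathways=isolated)


def project(graph: nx.Graph, mode: str) -> nx.Graph:
    """One-mode projection of the typed graph.

    ``gene_gene``: genes joined iff they share ≥1 pathway (via membership
    edges).  ``pathway_pathway``: pathways joined iff they share ≥1 member
    gene or are connected by an explicit pathway link.  Simple undirected
    graphs, no self-loops.
    """
    if mode not in ("gene_gene", "pathway_pathway"):
        raise InputError(f"mode must be 'gene_gene' or 'pathway_pathway', got {mode!r}")
    genes = [n for n, d in graph.nodes(data=True) if d.get("node_type") == "gene"]
    paths = [n for n, d in graph.nodes(data=True) if d.get("node_type") == "pathway"]
    out = nx.Graph()
    if mode == "gene_gene":
        out.add_nodes_from(genes)
        for p in paths:
            members = [v for v in graph.neighbors(p)
                       if graph.nodes[v].get("node_type") == "gene"
                       and graph[p][v].get("edge_type") == "membership"]
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    out.add_edge(a, b)
    else:
        out.add_nodes_from(paths)
        for gnode in genes:
            mem = [v for v in graph.neighbors(gnode)
                   if graph.nodes[v].get("node_type") == "pathway"
                   and graph[gnode][v].get("edge_type") == "membership"]
            for i, a in enumerate(mem):
                for b in mem[i + 1:]:
                    out.add_edge(a, b)
        for u, v, d in graph.edges(data=True):
            if d.get("edge_type") == "pathway_link":
                out.add_edge(u, v)
    return out
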