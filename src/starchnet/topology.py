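"""Graph-topology characterization of the assembled gene network.

Metrics follow the small-world / scale-free vocabulary: per-node degree and
its mean, mean shortest-path length over connected pairs of the largest
component, the Watts–Strogatz clustering coefficient (nodes of degree < 2
contribute 0 and are counted), component structure, and a heuristic
power-law diagnostic — ordinary least squares of log10(count) on
log10(degree).  The fit is descriptive, not a hypothesis test.

Because degree anecdotes in this kind of analysis mix graph views (a gene's
pathway memberships; a pathway's links to other pathways), metrics can be
computed on the full typed graph or on either one-mode projection, and the
JSON report always carries all three views.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .errors import InputError
from .network import project

__all__ = [
    "TopologySummary",
    "degree_profile",
    "average_path_length",
    "clustering_coefficient",
    "scale_free_fit",
    "summarize",
    "full_report",
]

VIEWS = ("full", "gene_gene", "pathway_pathway")


@dataclass
class TopologySummary:
    """Topology metrics of one graph view.

    ``average_path_length`` averages over connected node pairs of the main
    component; ``clustering_coefficient`` is the mean local clustering over
    main-component nodes.  ``powerlaw_exponent`` / ``fit_r2`` are ``None``
    when the degree distribution has fewer than 3 distinct degrees.
    """

    degrees: dict[str, int]
    average_degree: float
    average_path_length: float | None
    clustering_coefficient: float
    n_components: int
    main_component_size: int
    degree_distribution: dict[int, int]
    powerlaw_exponent: float | None
    fit_r2: float | None


def _view(graph: nx.Graph, view: str) -> nx.Graph:
    if view == "full":
        return graph
    if view in ("gene_gene", "pathway_pathway"):
        return project(graph, view)
    raise InputError(f"unknown view {view!r}; expected one of {VIEWS}")


def degree_profile(graph: nx.Graph, view: str = "full") -> tuple[dict[str, int], float]:
    """Per-node degree and its arithmetic mean in the selected view."""
    g = _view(graph, view)
    if g.number_of_nodes() == 0:
        raise InputError("empty graph has no degree profile")
    degrees = {str(n): int(d) for n, d in g.degree()}
    return degrees, float(np.mean(list(degrees.values())))


def _main_component(g: nx.Graph) -> set:
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(str(x) for x in c)))
    return comps[0]


def average_path_length(g: nx.Graph) -> float | None:
    """Mean shortest-path distance over unordered connected node pairs of
    the main component; ``None`` when the main component has no edge."""
    if g.number_of_nodes() == 0:
        raise InputError("empty graph has no path length")
    main = _main_component(g)
    if len(main) < 2:
        return None
    sub = g.subgraph(main)
    total, pairs = 0.0, 0
    for _src, dists in nx.all_pairs_shortest_path_length(sub):
        total += sum(dists.values())
        pairs += len(dists) - 1  # drop distance-0 self entry
    if pairs == 0:
        return None
    return total / pairs  # each unordered pair counted twice in both sums


def clustering_coefficient(g: nx.Graph) -> tuple[float, dict[str, float]]:
    """Watts–Strogatz global clustering over main-component nodes, plus the
    per-node local coefficients (all nodes)."""
    if g.number_of_nodes() == 0:
        raise InputError("empty graph has no clustering coefficient")
    local = {str(n): float(c) for n, c in nx.clustering(g).items()}
    main = _main_component(g)
    global_cc = float(np.mean([local[str(n)] for n in main]))
    return global_cc, local


def scale_free_fit(degree_distribution: dict[int, int]
                   ) -> tuple[float, float] | None:
    """Log–log least-squares diagnostic of the degree distribution.

    Regresses log10(count) on log10(degree) over degrees ≥ 1 with nonzero
    counts; returns ``(exponent, r²)`` with exponent = −slope, or ``None``
    (fit refused) with fewer than 3 distinct such degrees.
    """
    pts = [(k, c) for k, c in degree_distribution.items() if k >= 1 and c > 0]
    if len(pts) < 3:
        return None
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(r2)


def summarize(graph: nx.Graph, view: str = "full") -> TopologySummary:
    """All topology metrics of one view of the graph."""
    g = _view(graph, view)
    if g.number_of_nodes() == 0:
        raise InputError("empty graph has no topology summary")
    degrees = {str(n): int(d) for n, d in g.degree()}
    avg_deg = float(np.mean(list(degrees.values())))
    dist: dict[int, int] = {}
    for d in degrees.values():
        dist[d] = dist.get(d, 0) + 1
    comps = list(nx.connected_components(g))
    main = _main_component(g)
    cc, _local = clustering_coefficient(g)
    fit = scale_free_fit(dist)
    return TopologySummary(
        degrees=degrees,
        average_degree=avg_deg,
        average_path_length=average_path_length(g),
        clustering_coefficient=cc,
        n_components=len(comps),
        main_component_size=len(main),
        degree_distribution=dist,
        powerlaw_exponent=None if fit is None else fit[0],
        fit_r2=None if fit is None else fit[1],
    )


def full_report(graph: nx.Graph) -> dict:
    """Flat JSON-ready report carrying every view's metrics."""
    report: dict = {}
    for view in VIEWS:
        g = _view(graph, view)
        if g.number_of_nodes() == 0:
            report[view] = None
            continue
        s = summarize(graph, view)
        d = asdict(s)
        d["degree_distribution"] = {str(k): v for k, v in s.degree_distribution.items()}
        report[view] = d
    return report
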