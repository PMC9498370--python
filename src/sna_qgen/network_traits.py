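"""Per-pen duration-weighted aggression networks and the six centrality traits.

Each pen is an undirected graph over its full roster: nodes are animals
(fighters and non-fighters alike), an edge joins every dyad that fought, and
its weight is the total reciprocal-fight duration in seconds.  Six traits are
scored per animal — degree, weighted degree (strength), betweenness,
closeness, eigenvector centrality and the local clustering coefficient — and
square-root transformed, since fight-network scores are strongly
right-skewed.

Conventions (all configurable where noted):

* Betweenness and closeness treat edge weights as path *costs* (a long fight
  is a long path), the default of the usual graph libraries; an
  inverse-duration mode is available via ``weight_mode="inverse"``.
* Closeness on disconnected graphs uses the Wasserman-Faust component-size
  correction.
* Eigenvector centrality is the leading eigenvector of the weighted adjacency
  matrix by power iteration, rescaled so the best-connected node scores 1;
  nodes in non-dominant components score ~0.
* Clustering is the unweighted local proportion by default
  (``clustering_mode="barrat"`` gives the Barrat weighted variant).
* Isolated nodes score 0 on every trait.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

TRAITS = ["degree", "weighted_degree", "betweenness", "closeness",
          "eigenvector", "clustering"]

_POWER_TOL = 1e-12
_POWER_MAXIT = 10_000
_POWER_SHIFT = 0.05  # diagonal shift as a fraction of the max row sum


class DegeneratePenError(ValueError):
    """Raised for pens with fewer than two animals, where centralities are undefined."""


@dataclass
class WeightedAggressionGraph:
    """Undirected weighted fight network of one pen, isolated nodes included."""

    pen_id: str
    graph: nx.Graph

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()


def aggregate_fights(records) -> dict:
    """Sum fight durations per unordered dyad, per pen.

    Returns ``{pen_id: {frozenset({a, b}): total_duration_s}}``.
    """
    pens = defaultdict(lambda: defaultdict(float))
    for rec in records:
        pens[rec.pen_id][rec.dyad] += rec.duration
    return {pen: dict(dyads) for pen, dyads in pens.items()}


def build_graph(roster, dyads: dict) -> WeightedAggressionGraph:
    """Assemble the pen graph from its roster and aggregated dyad durations."""
    g = nx.Graph()
    g.add_nodes_from(roster.members)
    members = set(roster.members)
    for dyad, duration in dyads.items():
        a, b = sorted(dyad)
        for animal in (a, b):
            if animal not in members:
                raise ValueError(
                    f"dyad animal {animal!r} not in roster of pen {roster.pen_id!r}"
                )
        g.add_edge(a, b, weight=float(duration))
    return WeightedAggressionGraph(pen_id=roster.pen_id, graph=g)


def _check_node(g: WeightedAggressionGraph, v) -> None:
    if v not in g.graph:
        raise KeyError(f"animal {v!r} not in pen {g.pen_id!r}")


def degree_centrality(g: WeightedAggressionGraph, v) -> float:
    """Number of opponents of ``v`` divided by (n - 1)."""
    _check_node(g, v)
    if g.n < 2:
        raise DegeneratePenError(f"degenerate pen {g.pen_id!r} (n={g.n})")
    return g.graph.degree(v) / (g.n - 1)


def weighted_degree(g: WeightedAggressionGraph, v) -> float:
    """Strength: total seconds of fighting ``v`` was involved in."""
    _check_node(g, v)
    return float(g.graph.degree(v, weight="weight"))


def _cost_graph(g: WeightedAggressionGraph, weight_mode: str) -> nx.Graph:
    if weight_mode == "cost":
        return g.graph
    if weight_mode == "inverse":
        h = g.graph.copy()
        for _, _, d in h.edges(data=True):
            d["weight"] = 1.0 / d["weight"]
        return h
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def betweenness_centrality(g: WeightedAggressionGraph, v=None,
                           weight_mode: str = "cost"):
    """Brandes betweenness with durations as path costs, normalized to [0, 1].

    Fractional credit is shared over equally short paths; normalization is by
    (n-1)(n-2)/2 pairs.  Returns the dict of all nodes, or one value if ``v``
    is given.
    """
    if v is not None:
        _check_node(g, v)
    if any(d["weight"] < 0 for _, _, d in g.graph.edges(data=True)):
        raise ValueError("negative edge weight")
    scores = nx.betweenness_centrality(
        _cost_graph(g, weight_mode), normalized=True, weight="weight"
    )
    return scores if v is None else scores[v]


def closeness_centrality(g: WeightedAggressionGraph, v=None,
                         weight_mode: str = "cost"):
    """Weighted closeness with the Wasserman-Faust correction.

    For node v reachable from r-1 others: ((r-1)/sum of distances) * (r-1)/(n-1);
    0 for isolated nodes.
    """
    if v is not None:
        _check_node(g, v)
        return nx.closeness_centrality(
            _cost_graph(g, weight_mode), u=v, distance="weight", wf_improved=True
        )
    return nx.closeness_centrality(
        _cost_graph(g, weight_mode), distance="weight", wf_improved=True
    )


def eigenvector_centrality(g: WeightedAggressionGraph, v=None):
    """Leading-eigenvector score of the weighted adjacency, max node = 1.

    Power iteration from a uniform positive start vector to tolerance 1e-10;
    on disconnected graphs mass concentrates on the spectrally dominant
    component and other components score ~0.  An edgeless graph scores 0
    everywhere.
    """
    if v is not None:
        _check_node(g, v)
    nodes = list(g.graph.nodes)
    n = len(nodes)
    if g.graph.number_of_edges() == 0:
        scores = {u: 0.0 for u in nodes}
        return scores if v is None else scores[v]
    A = nx.to_numpy_array(g.graph, nodelist=nodes, weight="weight")
    # positive diagonal shift: leaves the leading eigenvector unchanged but
    # breaks the +/-lambda symmetry of bipartite components (paths, stars),
    # on which unshifted power iteration oscillates forever
    shift = _POWER_SHIFT * A.sum(axis=1).max()
    A = A + shift * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(_POWER_MAXIT):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0.0:  # start vector orthogonal to the image; cannot occur
            break        # from a positive start on a nonneg symmetric matrix
        y /= norm
        if np.linalg.norm(y - x) < _POWER_TOL:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"eigenvector power iteration did not converge in {_POWER_MAXIT} steps"
        )
    x = np.abs(x)
    x /= x.max()
    x[x < _POWER_TOL * 100] = 0.0  # numerical zeros in non-dominant components
    scores = {u: float(s) for u, s in zip(nodes, x)}
    return scores if v is None else scores[v]


def clustering_coefficient(g: WeightedAggressionGraph, v=None,
                           clustering_mode: str = "topological"):
    """Local clustering coefficient; 0 when a node has fewer than 2 neighbours.

    ``"topological"`` (default) ignores weights: realized / possible edges
    among the node's neighbours.  ``"barrat"`` is the weighted variant that
    credits each closed triangle by the mean weight of the two edges anchored
    at the focal node, relative to its strength.
    """
    if v is not None:
        _check_node(g, v)
    if clustering_mode == "topological":
        scores = nx.clustering(g.graph)
        scores = {u: float(s) for u, s in scores.items()}
    elif clustering_mode == "barrat":
        scores = {}
        for u in g.graph.nodes:
            nbrs = list(g.graph[u])
            k = len(nbrs)
            s = weighted_degree(g, u)
            if k < 2 or s == 0:
                scores[u] = 0.0
                continue
            total = 0.0
            for i in range(k):
                for j in range(i + 1, k):
                    a, b = nbrs[i], nbrs[j]
                    if g.graph.has_edge(a, b):
                        total += (g.graph[u][a]["weight"] + g.graph[u][b]["weight"]) / 2.0
            # Barrat: C_i = 1/(s_i (k_i - 1)) * sum_{jh in triangles} (w_ij + w_ih)/2
            scores[u] = total / (s * (k - 1))
    else:
        raise ValueError(f"unknown clustering_mode {clustering_mode!r}")
    return scores if v is None else scores[v]


def compute_all_traits(g: WeightedAggressionGraph,
                       weight_mode: str = "cost",
                       clustering_mode: str = "topological") -> pd.DataFrame:
    """Score every roster member on the six traits, raw and sqrt-transformed.

    Returns a DataFrame indexed by animal with columns ``pen_id``, the six
    raw traits and ``t_<trait>`` = sqrt(raw) for each.  Deterministic given
    the graph.
    """
    if g.n < 2:
        raise DegeneratePenError(f"degenerate pen {g.pen_id!r} (n={g.n})")
    bet = betweenness_centrality(g, weight_mode=weight_mode)
    clo = closeness_centrality(g, weight_mode=weight_mode)
    eig = eigenvector_centrality(g)
    clu = clustering_coefficient(g, clustering_mode=clustering_mode)
    rows = {}
    for v in g.graph.nodes:
        rows[v] = {
            "degree": degree_centrality(g, v),
            "weighted_degree": weighted_degree(g, v),
            "betweenness": bet[v],
            "closeness": clo[v],
            "eigenvector": eig[v],
            "clustering": clu[v],
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[TRAITS]
    df.insert(0, "pen_id", g.pen_id)
    for trait in TRAITS:
        df[f"t_{trait}"] = np.sqrt(df[trait])
    df.index.name = "animal"
    return df


def traits_from_records(records, rosters: dict, **kwargs) -> pd.DataFrame:
    """Fight records + rosters -> one trait table over all pens."""
    per_pen = aggregate_fights(records)
    frames = []
    for pen_id in sorted(rosters):
        g = build_graph(rosters[pen_id], per_pen.get(pen_id, {}))
        frames.append(compute_all_traits(g, **kwargs))
    return pd.concat(frames)


def export_edge_lists(records, path) -> None:
    """Write aggregated per-pen edges as pen_id,animal_a,animal_b,weight_s."""
    rows = []
    for pen_id, dyads in sorted(aggregate_fights(records).items()):
        for dyad, w in sorted(dyads.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(dyad)
            rows.append((pen_id, a, b, w))
    pd.DataFrame(rows, columns=["pen_id", "animal_a", "animal_b", "weight_s"]).to_csv(
        path, index=False
    )
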