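"""Per-patch topological predictors and network-level structure.

The predictor set combines five topological measures — degree, third-order
neighborhood, unweighted betweenness centrality, strength (probability-
weighted degree), and habitat availability (an area-weighted reachability
built on maximum-product path probabilities, after the probability-of-
connectivity index) — with the two patch-quality attributes HSI and area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "degree",
    "third_order_neighborhood",
    "betweenness",
    "strength",
    "habitat_availability",
    "component_census",
    "predictor_table",
    "ComponentCensus",
    "PREDICTOR_COLUMNS",
]

PREDICTOR_COLUMNS = [
    "degree",
    "neigh3",
    "betweenness",
    "strength",
    "habAv",
    "HSI",
    "area",
]


def degree(g: nx.Graph) -> dict:
    """Number of incident edges per patch."""
    return dict(g.degree())


def third_order_neighborhood(g: nx.Graph) -> dict:
    """Count of distinct patches within three edges of the focal patch."""
    out = {}
    for n in g.nodes:
        reach = nx.single_source_shortest_path_length(g, n, cutoff=3)
        out[n] = len(reach) - 1  # exclude the focal node itself
    return out


def betweenness(g: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness on the unweighted graph.

    Each unordered node pair (s, t) contributes sigma_st(v)/sigma_st to
    every intermediate node v; cross-component pairs contribute nothing.
    """
    return nx.betweenness_centrality(g, normalized=False)


def strength(g: nx.Graph) -> dict:
    """Sum of incident edge dispersal probabilities (weighted degree)."""
    return dict(g.degree(weight="probability"))


def habitat_availability(g: nx.Graph, include_self: bool = True) -> dict:
    """Area-weighted reachability HA_i = [a_i] + sum_j a_j * p*_ij.

    p*_ij is the maximum over paths of the product of edge probabilities,
    found as a shortest path on w = -log(probability); unreachable patches
    contribute nothing. ``include_self`` adds the patch's own area (the
    i = j term of the probability-of-connectivity double sum).
    """
    for _, _, d in g.edges(data=True):
        if d["probability"] <= 0:
            raise ValueError("edge probabilities must be positive")
    logw = {
        (u, v): -math.log(d["probability"]) for u, v, d in g.edges(data=True)
    }

    def w(u, v, _d):
        return logw.get((u, v), logw.get((v, u)))

    out = {}
    for n in g.nodes:
        dists = nx.single_source_dijkstra_path_length(g, n, weight=w)
        ha = g.nodes[n]["area"] if include_self else 0.0
        for m, dist in dists.items():
            if m == n:
                continue
            ha += g.nodes[m]["area"] * math.exp(-dist)
        out[n] = ha
    return out


@dataclass
class ComponentCensus:
    n_components: int
    component_id: dict
    giant_component_size: int

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for cid in self.component_id.values():
            counts[cid] = counts.get(cid, 0) + 1
        return sorted(counts.values(), reverse=True)


def component_census(g: nx.Graph) -> ComponentCensus:
    """Connected components; isolated patches are singleton components."""
    comps = list(nx.connected_components(g))
    cid = {}
    for k, comp in enumerate(comps):
        for n in comp:
            cid[n] = k
    giant = max((len(c) for c in comps), default=0)
    return ComponentCensus(
        n_components=len(comps), component_id=cid, giant_component_size=giant
    )


def predictor_table(g: nx.Graph, include_self: bool = True) -> pd.DataFrame:
    """All seven per-patch predictors, one row per patch."""
    deg = degree(g)
    n3 = third_order_neighborhood(g)
    btw = betweenness(g)
    stg = strength(g)
    hav = habitat_availability(g, include_self=include_self)
    rows = [
        {
            "patch_id": n,
            "degree": deg[n],
            "neigh3": n3[n],
            "betweenness": btw[n],
            "strength": stg[n],
            "habAv": hav[n],
            "HSI": g.nodes[n]["hsi"],
            "area": g.nodes[n]["area"],
        }
        for n in g.nodes
    ]
    return pd.DataFrame(rows).set_index("patch_id")
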