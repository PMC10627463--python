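"""Habitat-network construction under a dispersal-distance threshold.

Patches become nodes; an edge joins two patches when the least cumulative
cost of moving between them falls below a threshold derived from a
negative-exponential dispersal kernel:

    cost = log(prob) / log(p) * d0

where ``d0`` is the cost distance reached by a proportion ``p`` of
dispersers (p = 0.5 makes d0 the median dispersal distance) and ``prob`` is
the dispersal probability at that cost. Inverting at a probability cutoff
``prob_min`` (default 1e-4) gives the maximum cost at which an edge is still
drawn; each edge carries its cost and its kernel probability
``p ** (cost / d0)``.

Costs are measured patch boundary to patch boundary. On a uniform resistance
surface the default is exact Euclidean distance between patch polygons; an
8-neighbour grid least-cost mode supports arbitrary resistance surfaces.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd
from shapely.strtree import STRtree
import shapely

from .patches import PatchSet

__all__ = [
    "DispersalParams",
    "cost_threshold",
    "d0_for_max_distance",
    "edge_probability",
    "interpatch_costs",
    "build_network",
    "write_network_csv",
]


@dataclass(frozen=True)
class DispersalParams:
    """Kernel parameters: median-distance scale d0, shape p, edge cutoff."""

    d0: float  # metres; cost distance of the p-quantile disperser
    p: float = 0.5  # proportion of individuals reaching d0
    prob_min: float = 1e-4  # dispersal probability below which no edge forms

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if not 0 < self.prob_min < 1:
            raise ValueError("prob_min must be in (0, 1)")


def cost_threshold(params: DispersalParams) -> float:
    """Maximum cost at which an edge is drawn: log(prob_min)/log(p) * d0."""
    return math.log(params.prob_min) / math.log(params.p) * params.d0


def d0_for_max_distance(
    max_distance: float, p: float = 0.5, prob_min: float = 1e-4
) -> int:
    """Integer d0 whose cost threshold approximates ``max_distance``.

    Inverts :func:`cost_threshold`: d0 = max_distance * log(p)/log(prob_min),
    rounded to the nearest integer metre.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if not 0 < p < 1 or not 0 < prob_min < 1:
        raise ValueError("p and prob_min must be in (0, 1)")
    return round(max_distance * math.log(p) / math.log(prob_min))


def edge_probability(cost: float, params: DispersalParams) -> float:
    """Dispersal probability at a given cost: p ** (cost / d0)."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return params.p ** (cost / params.d0)


def interpatch_costs(
    patches: PatchSet,
    cost_cap: float,
    resistance: np.ndarray | None = None,
    mode: str = "euclidean",
) -> dict[tuple[int, int], float]:
    """Pairwise least costs between patches, up to ``cost_cap``.

    Returns a dict keyed by (patch_id_i, patch_id_j) with i < j; pairs with
    cost above the cap (or unreachable in grid mode) are absent.

    ``euclidean`` mode (default, valid for a uniform resistance surface)
    measures exact boundary-to-boundary distance between patch polygons.
    ``grid`` mode runs a multi-source Dijkstra over the 8-neighbour cell
    graph with step cost = mean of the endpoint resistances x centre-to-
    centre distance (diagonal steps x sqrt(2)); nodata/nonpositive
    resistance cells are untraversable.
    """
    if mode == "euclidean":
        return _euclidean_costs(patches, cost_cap)
    if mode == "grid":
        if resistance is None:
            resistance = np.ones_like(patches.labels, dtype=float)
        return _grid_costs(patches, resistance, cost_cap)
    raise ValueError(f"unknown mode {mode!r}")


def _euclidean_costs(patches: PatchSet, cost_cap: float):
    if len(patches) < 2:
        return {}
    ids = patches.patch_ids
    geoms = [patches.geometry(p) for p in patches]
    tree = STRtree(geoms)
    costs: dict[tuple[int, int], float] = {}
    for i, gi in enumerate(geoms):
        near = tree.query(gi, predicate="dwithin", distance=cost_cap)
        for j in near:
            if j <= i:
                continue
            d = float(shapely.distance(gi, geoms[j]))
            if d < cost_cap:
                costs[(ids[i], ids[int(j)])] = d
    return costs


_STEPS = [
    (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
    (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
    (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2)),
]


def _grid_costs(patches: PatchSet, resistance: np.ndarray, cost_cap: float):
    labels = patches.labels
    nrow, ncol = labels.shape
    res = np.asarray(resistance, dtype=float)
    traversable = np.isfinite(res) & (res > 0)
    cs = patches.cell_size
    costs: dict[tuple[int, int], float] = {}
    for patch in patches:
        pid = patch.patch_id
        dist = np.full(labels.shape, np.inf)
        heap: list[tuple[float, int, int]] = []
        for r, c in zip(patch.rows, patch.cols):
            dist[r, c] = 0.0
            heapq.heappush(heap, (0.0, r, c))
        reached: dict[int, float] = {}
        while heap:
            d, r, c = heapq.heappop(heap)
            if d > dist[r, c]:
                continue
            lab = labels[r, c]
            if lab != 0 and lab != pid and lab not in reached:
                reached[lab] = d
            for dr, dc, mult in _STEPS:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrow and 0 <= c2 < ncol):
                    continue
                if not (traversable[r, c] and traversable[r2, c2]):
                    continue
                step = 0.5 * (res[r, c] + res[r2, c2]) * cs * mult
                nd = d + step
                if nd < dist[r2, c2] and nd <= cost_cap:
                    dist[r2, c2] = nd
                    heapq.heappush(heap, (nd, r2, c2))
        for lab, d in reached.items():
            key = (min(pid, lab), max(pid, lab))
            if d < costs.get(key, np.inf):
                costs[key] = d
    return costs


def build_network(
    patches: PatchSet,
    costs: dict[tuple[int, int], float],
    params: DispersalParams,
    max_dispersal_distance: float | None = None,
) -> nx.Graph:
    """Assemble the habitat network for one dispersal-distance setting.

    Every patch becomes a node (attributes ``area``, ``hsi``); an undirected
    edge is drawn for each patch pair whose cost is strictly below the
    kernel's cost threshold, annotated with ``cost`` and ``probability``.
    The same cost table can therefore be filtered repeatedly to derive the
    networks of a whole distance sweep from one expensive pass.
    """
    threshold = cost_threshold(params)
    g = nx.Graph(
        d0=params.d0,
        p=params.p,
        prob_min=params.prob_min,
        cost_threshold=threshold,
        max_dispersal_distance=(
            max_dispersal_distance if max_dispersal_distance is not None else threshold
        ),
    )
    for patch in patches:
        g.add_node(patch.patch_id, area=patch.area, hsi=patch.hsi)
    for (i, j), cost in costs.items():
        if cost < threshold:
            g.add_edge(i, j, cost=float(cost), probability=edge_probability(cost, params))
    return g


def write_network_csv(g: nx.Graph, nodes_path, edges_path) -> None:
    nodes = pd.DataFrame(
        [
            {"patch_id": n, "area_m2": d.get("area"), "hsi": d.get("hsi")}
            for n, d in g.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "cost_m": d["cost"], "probability": d["probability"]}
            for u, v, d in g.edges(data=True)
        ]
    )
    nodes.to_csv(nodes_path, index=False)
    edges.to_csv(edges_path, index=False)
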