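"""District adjacency graphs and the ICAR precision structure.

An intrinsic conditional autoregressive (ICAR) prior on a vector of area
effects ``f`` has improper density proportional to
``exp(-tau/2 * f' Q f)`` where ``Q = diag(n_j) - A`` is the graph
Laplacian of the adjacency structure: ``n_j`` is the number of
neighbours of area ``j`` and ``A`` the 0/1 adjacency matrix.  ``Q`` is
rank-deficient — its null space is spanned by the indicator vectors of
the connected components — which is why fitting imposes one sum-to-zero
constraint per component.

The on-disk format is a plain-text neighbour list in the style used by
structured-additive-regression software: the first line holds the number
of regions ``D``; then, for each region, three lines — the region id,
its neighbour count, and the space-separated neighbour ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "AdjacencyGraph",
    "read_graph_file",
    "write_graph_file",
    "icar_precision",
    "connected_components",
]


class GraphError(ValueError):
    """Raised for malformed or inconsistent adjacency inputs."""


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour structure over integer region ids.

    Region ids are arbitrary integers (e.g. district codes 1..30); they
    are mapped internally to dense 0-based indices in the order of
    ``region_ids``, and all outputs report the original ids.
    """

    region_ids: list[int]
    neighbors: dict[int, set[int]]
    labels: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        ids = list(self.region_ids)
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphError(f"duplicate region id(s): {dup}")
        idset = set(ids)
        for j, nbrs in self.neighbors.items():
            if j not in idset:
                raise GraphError(f"neighbor list for unknown region {j}")
            if j in nbrs:
                raise GraphError(f"self-loop at region {j}")
            for k in nbrs:
                if k not in idset:
                    raise GraphError(f"region {j} lists unknown neighbor {k}")
                if j not in self.neighbors.get(k, set()):
                    raise GraphError(
                        f"asymmetric adjacency: {k} is a neighbor of {j} "
                        f"but not conversely"
                    )
        # regions with no entry get an empty neighbour set
        for j in ids:
            self.neighbors.setdefault(j, set())

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: int) -> int:
        return self.region_ids.index(region_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for j, nbrs in self.neighbors.items():
            g.add_edges_from((j, k) for k in nbrs if j < k)
        return g

    def degree(self) -> np.ndarray:
        return np.array([len(self.neighbors[j]) for j in self.region_ids])


def read_graph_file(path: str | Path) -> AdjacencyGraph:
    """Read a plain-text neighbour-list graph file.

    Raises :class:`GraphError` on duplicate ids, self-loops or an
    asymmetric adjacency (naming the offending pair).
    """
    tokens = Path(path).read_text().split()
    if not tokens:
        raise GraphError(f"empty graph file: {path}")
    it = iter(tokens)
    try:
        d = int(next(it))
        region_ids: list[int] = []
        neighbors: dict[int, set[int]] = {}
        for _ in range(d):
            rid = int(next(it))
            if rid in neighbors:
                raise GraphError(f"duplicate region id: {rid}")
            cnt = int(next(it))
            neighbors[rid] = {int(next(it)) for _ in range(cnt)}
            region_ids.append(rid)
    except StopIteration:
        raise GraphError(f"truncated graph file: {path}") from None
    return AdjacencyGraph(region_ids=region_ids, neighbors=neighbors)


def write_graph_file(graph: AdjacencyGraph, path: str | Path) -> None:
    lines = [str(graph.n_regions)]
    for rid in graph.region_ids:
        nbrs = sorted(graph.neighbors[rid])
        lines += [str(rid), str(len(nbrs)), " ".join(map(str, nbrs))]
    Path(path).write_text("\n".join(lines) + "\n")


def icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """ICAR precision structure ``Q = diag(n_j) - adjacency``.

    Rows sum to zero; rank is ``D - (number of connected components)``.
    Returned in the dense index order of ``graph.region_ids``.
    """
    d = graph.n_regions
    pos = {rid: i for i, rid in enumerate(graph.region_ids)}
    q = np.zeros((d, d))
    for j, nbrs in graph.neighbors.items():
        q[pos[j], pos[j]] = len(nbrs)
        for k in nbrs:
            q[pos[j], pos[k]] = -1.0
    return q


def adjacency_from_geojson(
    path: str | Path, id_property: str = "district"
) -> AdjacencyGraph:
    """Build adjacency from touching GeoJSON polygons.

    Never the default source of adjacency — neighbour-list files are the
    source of truth — but useful to bootstrap a ``.gra`` file from a map.
    Two regions are neighbours when their geometries intersect (touch).
    """
    import json

    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    geoms: dict[int, object] = {}
    for feat in gj["features"]:
        rid = int(feat["properties"][id_property])
        if rid in geoms:
            raise GraphError(f"duplicate region id: {rid}")
        geoms[rid] = shape(feat["geometry"])
    ids = list(geoms)
    neighbors: dict[int, set[int]] = {rid: set() for rid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if geoms[a].intersects(geoms[b]):
                neighbors[a].add(b)
                neighbors[b].add(a)
    return AdjacencyGraph(region_ids=ids, neighbors=neighbors)


def connected_components(graph: AdjacencyGraph) -> dict[int, int]:
    """Component label (0-based, by smallest member id) per region id."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph.to_networkx())),
        key=lambda c: c[0],
    )
    return {rid: lab for lab, members in enumerate(comps) for rid in members}
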