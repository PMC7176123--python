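"""District adjacency structures and the intrinsic-CAR precision matrix.

Areas are relabelled to a contiguous ``1..J`` index in order of first
appearance in the input; original codes are kept on the graph so every
downstream table can be joined back to the source geography.  The ICAR
precision ``Q`` has ``Q[j, j] = m_j`` (neighbour count) and ``Q[j, l] = -1``
for neighbouring pairs; it is improper, with one null eigenvector per
connected component.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np


class AdjacencyError(ValueError):
    """Raised when an adjacency source violates the graph contract."""


@dataclass(frozen=True)
class District:
    """One areal unit: 1-based model index plus its source code."""

    index: int
    code: str
    province: str | None = None


@dataclass
class AdjacencyGraph:
    """Symmetric, loop-free neighbour structure over J areas.

    ``neighbours[j]`` holds the 0-based neighbour indices of area ``j``
    (0-based internally; the public ``districts`` carry the 1-based index).
    """

    n_areas: int
    neighbours: list[list[int]]
    codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.codes:
            self.codes = [str(i + 1) for i in range(self.n_areas)]
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_areas < 1:
            raise AdjacencyError("graph must contain at least one area")
        if len(self.neighbours) != self.n_areas:
            raise AdjacencyError(
                f"neighbour list length {len(self.neighbours)} != n_areas {self.n_areas}"
            )
        if len(set(self.codes)) != self.n_areas:
            raise AdjacencyError("area codes are not unique")
        for j, nbrs in enumerate(self.neighbours):
            if j in nbrs:
                raise AdjacencyError(f"self-loop at area {j + 1}")
            if len(set(nbrs)) != len(nbrs):
                raise AdjacencyError(f"duplicate neighbour entries at area {j + 1}")
            for l in nbrs:
                if not (0 <= l < self.n_areas):
                    raise AdjacencyError(f"neighbour index {l + 1} out of range at area {j + 1}")
                if j not in self.neighbours[l]:
                    raise AdjacencyError(
                        f"asymmetric adjacency: area {j + 1} lists {l + 1} "
                        f"but {l + 1} does not list {j + 1}"
                    )
        if any(len(nbrs) == 0 for nbrs in self.neighbours):
            islands = [self.codes[j] for j, n in enumerate(self.neighbours) if not n]
            warnings.warn(
                f"graph contains island area(s) {islands}: their structured "
                "spatial effect is fixed at 0",
                stacklevel=3,
            )

    # -- views ------------------------------------------------------------
    @property
    def n_neighbours(self) -> np.ndarray:
        """Per-area neighbour count ``m_j``."""
        return np.array([len(n) for n in self.neighbours], dtype=int)

    @property
    def districts(self) -> list[District]:
        return [District(index=j + 1, code=c) for j, c in enumerate(self.codes)]

    @property
    def islands(self) -> np.ndarray:
        """0-based indices of areas with no neighbours."""
        return np.flatnonzero(self.n_neighbours == 0)

    def edges(self) -> list[tuple[int, int]]:
        """Unique undirected edges as 0-based (j, l) with j < l."""
        return [(j, l) for j, nbrs in enumerate(self.neighbours) for l in nbrs if j < l]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]


@dataclass(frozen=True)
class IcarStructure:
    """Explicit ICAR precision matrix and its rank deficiency."""

    Q: np.ndarray
    n_components: int

    @property
    def rank(self) -> int:
        return self.Q.shape[0] - self.n_components


def icar_structure(graph: AdjacencyGraph) -> IcarStructure:
    """Build the (improper) ICAR precision Q = diag(m) - A for *graph*."""
    J = graph.n_areas
    Q = np.zeros((J, J))
    for j, nbrs in enumerate(graph.neighbours):
        Q[j, j] = len(nbrs)
        for l in nbrs:
            Q[j, l] = -1.0
    n_comp = len(graph.connected_components())
    return IcarStructure(Q=Q, n_components=n_comp)


def lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency grid of ``rows × cols`` areas (row-major codes ``r{r}c{c}``)."""
    if rows < 1 or cols < 1:
        raise AdjacencyError("lattice dimensions must be positive")
    J = rows * cols
    neighbours: list[list[int]] = [[] for _ in range(J)]
    for r in range(rows):
        for c in range(cols):
            j = r * cols + c
            if c + 1 < cols:
                neighbours[j].append(j + 1)
                neighbours[j + 1].append(j)
            if r + 1 < rows:
                neighbours[j].append(j + cols)
                neighbours[j + cols].append(j)
    codes = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    with warnings.catch_warnings():
        if J == 1:
            warnings.simplefilter("always")
        return AdjacencyGraph(n_areas=J, neighbours=neighbours, codes=codes)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECTS = ("winbugs_adj", "edge_list", "geojson_polygons")


def read_adjacency(
    source: str | Path,
    dialect: str,
    id_property: str = "id",
) -> AdjacencyGraph:
    """Read an adjacency structure.

    Dialects
    --------
    ``winbugs_adj``
        Three integer vectors ``num`` (per-area neighbour counts), ``adj``
        (concatenated 1-based neighbour lists) and ``sumNumNeigh``.
    ``edge_list``
        Two-column CSV of area codes, one undirected edge per row; isolated
        areas may be declared as a row with an empty second column.
    ``geojson_polygons``
        FeatureCollection of polygons; queen contiguity (any shared boundary
        point after snapping coordinates at 1e-8 degrees).  *id_property*
        names the feature property holding the area code.
    """
    if dialect not in _DIALECTS:
        raise AdjacencyError(f"unknown adjacency dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(source)
    if dialect == "edge_list":
        return _read_edge_list(path)
    if dialect == "winbugs_adj":
        return _read_winbugs(path)
    return _read_geojson(path, id_property)


def _read_edge_list(path: Path) -> AdjacencyGraph:
    codes: list[str] = []
    index: dict[str, int] = {}

    def intern(code: str) -> int:
        if code not in index:
            index[code] = len(codes)
            codes.append(code)
        return index[code]

    pairs: list[tuple[int, int]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        a = intern(parts[0])
        if len(parts) < 2 or not parts[1]:
            continue  # isolated-area declaration
        b = intern(parts[1])
        if a == b:
            raise AdjacencyError(f"self-loop at area {parts[0]}")
        pairs.append((a, b))
    if not codes:
        raise AdjacencyError(f"no areas found in edge list {path}")
    neighbours: list[list[int]] = [[] for _ in codes]
    for a, b in pairs:
        if b not in neighbours[a]:
            neighbours[a].append(b)
        if a not in neighbours[b]:
            neighbours[b].append(a)
    return AdjacencyGraph(n_areas=len(codes), neighbours=neighbours, codes=codes)


def _read_winbugs(path: Path) -> AdjacencyGraph:
    """Parse the GeoBUGS ``num``/``adj``/``sumNumNeigh`` vectors.

    Accepts the R-ish ``num = c(...)`` syntax as well as bare whitespace- or
    comma-separated integer blocks headed by the vector name.
    """
    text = path.read_text()
    vectors: dict[str, list[int]] = {}
    for name in ("num", "adj", "sumNumNeigh"):
        start = text.find(name)
        if start < 0:
            if name == "sumNumNeigh":
                continue
            raise AdjacencyError(f"winbugs_adj source missing vector {name!r}")
        chunk = text[start + len(name):]
        # consume up to the next named vector
        ends = [chunk.find(n) for n in ("num", "adj", "sumNumNeigh") if chunk.find(n) > 0]
        if ends:
            chunk = chunk[: min(ends)]
        tokens = (
            chunk.replace("=", " ").replace("c(", " ").replace("(", " ")
            .replace(")", " ").replace(",", " ").split()
        )
        vals = []
        for tok in tokens:
            try:
                vals.append(int(tok))
            except ValueError:
                break
        vectors[name] = vals
    num = vectors["num"]
    adj = vectors["adj"]
    if sum(num) != len(adj):
        raise AdjacencyError(
            f"winbugs_adj inconsistency: sum(num)={sum(num)} but adj has {len(adj)} entries"
        )
    if "sumNumNeigh" in vectors and vectors["sumNumNeigh"]:
        declared = vectors["sumNumNeigh"][0]
        if declared != len(adj):
            raise AdjacencyError(
                f"winbugs_adj sumNumNeigh={declared} disagrees with adj length {len(adj)}"
            )
    J = len(num)
    neighbours: list[list[int]] = []
    pos = 0
    for m in num:
        block = adj[pos: pos + m]
        neighbours.append([b - 1 for b in block])
        pos += m
    for j, nbrs in enumerate(neighbours):
        for l in nbrs:
            if not (0 <= l < J):
                raise AdjacencyError(f"adj entry {l + 1} out of range for J={J}")
    return AdjacencyGraph(n_areas=J, neighbours=neighbours)


def write_winbugs(graph: AdjacencyGraph, path: str | Path) -> None:
    """Write the graph in the GeoBUGS num/adj/sumNumNeigh dialect (round-trips)."""
    num = [len(n) for n in graph.neighbours]
    adj = [l + 1 for nbrs in graph.neighbours for l in nbrs]
    lines = [
        "num = c(" + ", ".join(map(str, num)) + ")",
        "adj = c(" + ", ".join(map(str, adj)) + ")",
        f"sumNumNeigh = {len(adj)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_geojson(path: Path, id_property: str) -> AdjacencyGraph:
    from shapely import set_precision
    from shapely.geometry import shape

    fc = json.loads(path.read_text())
    if fc.get("type") != "FeatureCollection":
        raise AdjacencyError("geojson_polygons source must be a FeatureCollection")
    codes: list[str] = []
    geoms = []
    for k, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        code = props.get(id_property, feat.get("id"))
        if code is None:
            raise AdjacencyError(f"feature {k} has no {id_property!r} property or id")
        codes.append(str(code))
        geoms.append(set_precision(shape(feat["geometry"]), 1e-8))
    if not geoms:
        raise AdjacencyError(f"no polygon features in {path}")
    J = len(geoms)
    neighbours: list[list[int]] = [[] for _ in range(J)]
    for a in range(J):
        for b in range(a + 1, J):
            # queen contiguity: any shared boundary point
            if geoms[a].intersects(geoms[b]) and not geoms[a].disjoint(geoms[b]):
                if not geoms[a].intersection(geoms[b]).is_empty:
                    neighbours[a].append(b)
                    neighbours[b].append(a)
    return AdjacencyGraph(n_areas=J, neighbours=neighbours, codes=codes)
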