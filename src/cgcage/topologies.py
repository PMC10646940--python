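"""Named cage topology graphs with ideal vertex geometry.

A topology graph types each vertex with the arity (2, 3 or 4) of the
building block it hosts and an ideal unit-scale position; edges (multi-edges
permitted) are the inter-building-block bonds to be formed.  The registry
covers the topologies commonly realised by metal-organic and organic cages:
``TriXDiY`` denotes X tritopic + Y ditopic blocks, ``TetX...`` tetratopic,
and the ``X_2`` subscript marks an alternative graph at the same
stoichiometry.

Ideal positions are centred on the origin and normalised to unit
circumradius; assembly rescales them.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class Vertex:
    id: int
    arity: int
    position: tuple[float, float, float]


@dataclass
class TopologyGraph:
    name: str
    vertices: list[Vertex]
    edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_building_blocks(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def vertex(self, vid: int) -> Vertex:
        for v in self.vertices:
            if v.id == vid:
                return v
        raise KeyError(f"no vertex {vid} in topology {self.name}")

    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.vertices])

    def arities(self) -> dict[int, int]:
        return {v.id: v.arity for v in self.vertices}

    def incident_edges(self, vid: int) -> list[int]:
        """Indices into ``edges`` of the edges touching ``vid``, in edge order."""
        return [i for i, (u, w) in enumerate(self.edges) if vid in (u, w)]

    def neighbours(self, vid: int) -> list[int]:
        """Neighbour vertex ids in incident-edge order (repeats for multi-edges)."""
        out = []
        for u, w in self.edges:
            if u == vid:
                out.append(w)
            elif w == vid:
                out.append(u)
        return out

    def multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(v.id for v in self.vertices)
        g.add_edges_from(self.edges)
        return g

    def composition(self) -> dict[int, int]:
        """Number of vertices per arity, e.g. {3: 4, 2: 6} for Tri4Di6."""
        comp: dict[int, int] = {}
        for v in self.vertices:
            comp[v.arity] = comp.get(v.arity, 0) + 1
        return dict(sorted(comp.items(), reverse=True))

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "vertices": [
                    {"id": v.id, "arity": v.arity, "position": list(v.position)}
                    for v in self.vertices
                ],
                "edges": [list(e) for e in self.edges],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TopologyGraph":
        doc = json.loads(text)
        return cls(
            name=doc["name"],
            vertices=[
                Vertex(int(v["id"]), int(v["arity"]), tuple(float(x) for x in v["position"]))
                for v in doc["vertices"]
            ],
            edges=[(int(u), int(w)) for u, w in doc["edges"]],
        )


def validate_graph(g: TopologyGraph) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    violations: list[str] = []
    mg = g.multigraph()
    for v in g.vertices:
        deg = mg.degree(v.id)
        if deg != v.arity:
            violations.append(f"vertex {v.id}: degree {deg} != arity {v.arity}")
    if sum(v.arity for v in g.vertices) != 2 * len(g.edges):
        violations.append("handshake: sum of arities != 2 * n_edges")
    if g.vertices and not nx.is_connected(mg):
        violations.append("graph is not connected")
    # a ditopic block cannot bind the same partner vertex twice
    for v in g.vertices:
        if v.arity == 2:
            nbrs = g.neighbours(v.id)
            if len(nbrs) == 2 and nbrs[0] == nbrs[1]:
                violations.append(
                    f"2-arity vertex {v.id} is multi-bonded to vertex {nbrs[0]}"
                )
    return violations


# ---------------------------------------------------------------------------
# ideal polyhedron vertex sets (unit circumradius after normalisation)

def _normalise(points: np.ndarray) -> np.ndarray:
    points = points - points.mean(axis=0)
    return points / np.abs(np.linalg.norm(points, axis=1)).max()


def _tetrahedron() -> np.ndarray:
    return np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) / math.sqrt(3)


def _octahedron() -> np.ndarray:
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )


def _cube() -> np.ndarray:
    return np.array(list(itertools.product([-1, 1], repeat=3)), float) / math.sqrt(3)


def _trigonal_prism() -> np.ndarray:
    # all edges equal: triangle edge s = rho * sqrt(3), height h = s
    rho = 1.0
    h = rho * math.sqrt(3.0)
    pts = []
    for z in (h / 2, -h / 2):
        for k in range(3):
            phi = 2 * math.pi * k / 3
            pts.append([rho * math.cos(phi), rho * math.sin(phi), z])
    return _normalise(np.array(pts))


def _square_antiprism() -> np.ndarray:
    # all edges equal: h^2 = sqrt(2) * rho^2
    rho = 1.0
    h = math.sqrt(math.sqrt(2.0)) * rho
    pts = []
    for z, off in ((h / 2, 0.0), (-h / 2, math.pi / 4)):
        for k in range(4):
            phi = 2 * math.pi * k / 4 + off
            pts.append([rho * math.cos(phi), rho * math.sin(phi), z])
    return _normalise(np.array(pts))


def _cuboctahedron() -> np.ndarray:
    pts = []
    for signs in itertools.product([-1, 1], repeat=2):
        pts.append([signs[0], signs[1], 0])
        pts.append([signs[0], 0, signs[1]])
        pts.append([0, signs[0], signs[1]])
    return np.array(pts, float) / math.sqrt(2)


def _polyhedron_edges(points: np.ndarray, tol: float = 1e-6) -> list[tuple[int, int]]:
    """Edges = vertex pairs at the minimal pairwise distance (regular solids)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    dmin = d[d > tol].min()
    return [(i, j) for i in range(n) for j in range(i + 1, n) if d[i, j] < dmin + tol]


def _edge_midpoint_topology(name: str, poly: np.ndarray, arity: int) -> TopologyGraph:
    """Polytopic blocks on polyhedron vertices, ditopic blocks on edge midpoints."""
    edges_poly = _polyhedron_edges(poly)
    n_poly = len(poly)
    vertices = [Vertex(i, arity, tuple(poly[i])) for i in range(n_poly)]
    edges: list[tuple[int, int]] = []
    pts = list(poly)
    for k, (i, j) in enumerate(edges_poly):
        vid = n_poly + k
        mid = 0.5 * (poly[i] + poly[j])
        pts.append(mid)
        vertices.append(Vertex(vid, 2, tuple(mid)))
        edges.append((i, vid))
        edges.append((j, vid))
    allpts = _normalise(np.array(pts))
    vertices = [Vertex(v.id, v.arity, tuple(allpts[k])) for k, v in enumerate(vertices)]
    return TopologyGraph(name, vertices, edges)


def _bipyramid_like(name: str, polar_arity: int, n_eq: int) -> TopologyGraph:
    """Two polytopic poles bridged by n_eq equatorial ditopic blocks."""
    vertices = [
        Vertex(0, polar_arity, (0.0, 0.0, 1.0)),
        Vertex(1, polar_arity, (0.0, 0.0, -1.0)),
    ]
    edges = []
    for k in range(n_eq):
        phi = 2 * math.pi * k / n_eq
        vid = 2 + k
        vertices.append(Vertex(vid, 2, (math.cos(phi), math.sin(phi), 0.0)))
        edges.append((0, vid))
        edges.append((1, vid))
    return TopologyGraph(name, vertices, edges)


def _bridged_polytopic(
    name: str,
    poly: np.ndarray,
    arity: int,
    bridges: list[tuple[int, int, int]],
) -> TopologyGraph:
    """Polytopic blocks on ``poly`` joined by ditopic bridges.

    ``bridges`` lists (i, j, multiplicity); parallel bridges are offset
    perpendicular to the i-j axis so positions stay distinct.
    """
    n_poly = len(poly)
    vertices = [Vertex(i, arity, tuple(poly[i])) for i in range(n_poly)]
    edges: list[tuple[int, int]] = []
    pts = list(poly)
    vid = n_poly
    for i, j, mult in bridges:
        mid = 0.5 * (poly[i] + poly[j])
        axis = poly[j] - poly[i]
        ref = poly[i] + poly[j]
        if np.linalg.norm(ref) < 1e-9:
            ref = np.array([0.0, 0.0, 1.0])
        perp = np.cross(axis, ref)
        nperp = np.linalg.norm(perp)
        perp = perp / nperp if nperp > 1e-9 else np.array([0.0, 0.0, 1.0])
        if mult == 1:
            offsets = [np.zeros(3)]
        else:
            span = 0.35 * np.linalg.norm(axis)
            offsets = [
                (t - (mult - 1) / 2) / max(mult - 1, 1) * 2 * span * perp
                for t in range(mult)
            ]
        for off in offsets:
            pts.append(mid + off)
            vertices.append(Vertex(vid, 2, tuple(mid + off)))
            edges.append((i, vid))
            edges.append((j, vid))
            vid += 1
    allpts = _normalise(np.array(pts))
    vertices = [Vertex(v.id, v.arity, tuple(allpts[k])) for k, v in enumerate(vertices)]
    return TopologyGraph(name, vertices, edges)


def _tet6tri8() -> TopologyGraph:
    oct_ = _octahedron()
    cube = _cube()
    vertices = [Vertex(i, 4, tuple(oct_[i])) for i in range(6)]
    vertices += [Vertex(6 + i, 3, tuple(cube[i])) for i in range(8)]
    edges = []
    for i in range(6):
        axis = int(np.argmax(np.abs(oct_[i])))
        sign = math.copysign(1.0, oct_[i][axis])
        for j in range(8):
            if math.copysign(1.0, cube[j][axis]) == sign:
                edges.append((i, 6 + j))
    return TopologyGraph("Tet6Tri8", vertices, edges)


def _build_registry() -> dict[str, TopologyGraph]:
    tet = _tetrahedron()
    reg = {}

    def add(g: TopologyGraph) -> None:
        bad = validate_graph(g)
        if bad:  # pragma: no cover - construction-time sanity
            raise AssertionError(f"{g.name}: {bad}")
        reg[g.name] = g

    add(_bipyramid_like("Tri2Di3", 3, 3))
    add(_bipyramid_like("Tet2Di4", 4, 4))
    add(_edge_midpoint_topology("Tri4Di6", tet, 3))
    # alternative 4+6 graph: doubled bridges A-B and C-D, singles A-C and B-D
    add(
        _bridged_polytopic(
            "Tri4_2Di6", tet, 3, [(0, 1, 2), (2, 3, 2), (0, 2, 1), (1, 3, 1)]
        )
    )
    add(_edge_midpoint_topology("Tri6Di9", _trigonal_prism(), 3))
    add(_edge_midpoint_topology("Tri8Di12", _cube(), 3))
    # double-walled tetrahedron: K4 bridges plus a doubled perfect matching
    add(
        _bridged_polytopic(
            "Tet4_2Di8",
            tet,
            4,
            [(0, 1, 2), (2, 3, 2), (0, 2, 1), (0, 3, 1), (1, 2, 1), (1, 3, 1)],
        )
    )
    add(_edge_midpoint_topology("Tet6Di12", _octahedron(), 4))
    add(_edge_midpoint_topology("Tet8Di16", _square_antiprism(), 4))
    add(_edge_midpoint_topology("Tet12Di24", _cuboctahedron(), 4))
    add(_tet6tri8())
    return reg


_REGISTRY: dict[str, TopologyGraph] = _build_registry()


def get_topology(name: str) -> TopologyGraph:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown topology {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_topology(g: TopologyGraph, overwrite: bool = False) -> None:
    """Add a custom validated graph to the registry."""
    if g.name in _REGISTRY and not overwrite:
        raise ValueError(f"topology {g.name!r} already registered")
    bad = validate_graph(g)
    if bad:
        raise ValueError(f"invalid topology graph: {bad}")
    _REGISTRY[g.name] = g


_BUILTIN_NAMES = frozenset(_REGISTRY)


def unregister_topology(name: str) -> None:
    if name in _BUILTIN_NAMES:
        raise ValueError(f"cannot remove built-in topology {name!r}")
    _REGISTRY.pop(name, None)


def list_topologies() -> list[tuple[str, dict[int, int], int]]:
    """Alphabetical (name, composition-by-arity, n_building_blocks) listing."""
    return [
        (name, _REGISTRY[name].composition(), _REGISTRY[name].n_building_blocks)
        for name in sorted(_REGISTRY)
    ]


def ideal_vertex_angles(name: str, vertex: int) -> list[float]:
    """Pairwise angles (degrees, sorted) between ideal edge directions at a vertex."""
    g = get_topology(name)
    v = g.vertex(vertex)
    if v.arity < 2:
        raise ValueError(f"vertex {vertex} has arity < 2")
    pos = np.array(v.position)
    dirs = []
    for nbr in g.neighbours(vertex):
        d = np.array(g.vertex(nbr).position) - pos
        dirs.append(d / np.linalg.norm(d))
    angles = []
    for u, w in itertools.combinations(dirs, 2):
        c = np.clip(np.dot(u, w), -1.0, 1.0)
        angles.append(math.degrees(math.acos(c)))
    return sorted(angles)
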