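"""Assemble bead-resolution cage models on topology graphs.

Placement rigidly moves each building block to its (scaled) ideal vertex
position and rotates it so its binder directions superpose onto the
directions of its incident edges (best orthogonal superposition over all
binder-to-edge assignments; ties broken by the lexicographically first
assignment).  Bond formation then adds exactly one inter-building-block bond
per topology edge plus the angle and torsion terms that encode the target
internal geometry.

The preorganisation torsion is "alchemical": it acts on the quadruple
(b, a, a, b) of a ditopic block and its two bonded partners even though the
two a beads are joined through c rather than directly; restricting it to 0
forces the two binding sites to face the same direction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .beads import BeadSpec, BuildingBlock, mixed_bond_length
from .topologies import TopologyGraph

#: torsion phase (degrees) putting the minimum of k(1 + cos(p*phi - phi0))
#: at phi = 0 for p = 1
TORSION_PHASE_DEG = 180.0


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    r0: float
    constructed: bool = False


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # apex
    k: int
    theta0: float  # degrees


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    phi0: float = TORSION_PHASE_DEG  # degrees
    p: int = 1


@dataclass
class CageModel:
    """An assembled bead system: coordinates plus complete term lists."""

    topology: str
    coords: np.ndarray
    bead_specs: list[BeadSpec]
    bead_owner: list[int]  # owning topology vertex per bead
    block_kind: dict[int, str]  # vertex id -> building-block kind
    block_slices: dict[int, tuple[int, int]]  # vertex id -> [start, stop) bead range
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)
    torsion_state: str = "on"

    @property
    def n_beads(self) -> int:
        return len(self.bead_specs)

    @property
    def n_building_blocks(self) -> int:
        return len(self.block_slices)

    @property
    def classes(self) -> list[str]:
        return [s.class_label for s in self.bead_specs]

    def constructed_bonds(self) -> list[BondTerm]:
        return [b for b in self.bonds if b.constructed]

    def intra_block_bonds(self) -> list[BondTerm]:
        return [b for b in self.bonds if not b.constructed]

    def exclusion_exempt_pairs(self) -> set[tuple[int, int]]:
        """All bead pairs separated by <= 2 bonds (excluded-volume off)."""
        n = self.n_beads
        adj = np.zeros((n, n), dtype=bool)
        for b in self.bonds:
            adj[b.i, b.j] = adj[b.j, b.i] = True
        two = (adj.astype(np.int64) @ adj.astype(np.int64)) > 0
        exempt = adj | two
        return {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if exempt[i, j]
        }

    def nonexempt_pairs(self) -> np.ndarray:
        """Index array (P, 2) of pairs subject to excluded volume."""
        n = self.n_beads
        adj = np.zeros((n, n), dtype=bool)
        for b in self.bonds:
            adj[b.i, b.j] = adj[b.j, b.i] = True
        two = (adj.astype(np.int64) @ adj.astype(np.int64)) > 0
        exempt = adj | two
        iu, ju = np.triu_indices(n, k=1)
        keep = ~exempt[iu, ju]
        return np.stack([iu[keep], ju[keep]], axis=1)


class AssemblyError(ValueError):
    pass


@dataclass
class Placement:
    """Result of rigid placement: global coordinates and binder bookkeeping."""

    coords: np.ndarray
    bead_specs: list[BeadSpec]
    bead_owner: list[int]
    block_slices: dict[int, tuple[int, int]]
    #: (vertex id, edge index) -> global bead index of the binder serving it
    binder_for_edge: dict[tuple[int, int], int]
    scale: float


def _align_block(
    block: BuildingBlock, targets: np.ndarray
) -> tuple[Rotation, tuple[int, ...]]:
    """Best rotation mapping binder directions onto edge target directions.

    Tries every assignment of binders to edges; returns the rotation and the
    winning assignment ``perm`` where ``perm[k]`` is the binder (local index
    into ``binder_indices``) serving incident edge k.  Ties break to the
    lexicographically first permutation.
    """
    local = block.coords[block.binder_indices]
    bdirs = local / np.linalg.norm(local, axis=1, keepdims=True)
    best: tuple[float, tuple[int, ...], Rotation] | None = None
    for perm in itertools.permutations(range(len(block.binder_indices))):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # 2-vector alignment can be degenerate
            rot, rssd = Rotation.align_vectors(targets, bdirs[list(perm)])
        if best is None or rssd < best[0] - 1e-12:
            best = (rssd, perm, rot)
    assert best is not None
    return best[2], best[1]


def place_building_blocks(
    g: TopologyGraph,
    blocks: dict[int, BuildingBlock],
    scale: float | None = None,
    min_clearance: float = 1.2,
) -> Placement:
    """Rigidly place one building block per topology vertex.

    ``scale`` multiplies the unit-circumradius ideal positions; when None the
    smallest scale is chosen such that every constructed bond can reach its
    equilibrium length and no inter-block bead pair sits closer than
    ``min_clearance`` times the mean bead sigma.
    """
    for v in g.vertices:
        if v.id not in blocks:
            raise AssemblyError(f"no building block supplied for vertex {v.id}")
        if blocks[v.id].arity != v.arity:
            raise AssemblyError(
                f"vertex {v.id} requires arity {v.arity}, "
                f"got a {blocks[v.id].kind} block (arity {blocks[v.id].arity})"
            )

    pos = {v.id: np.array(v.position) for v in g.vertices}
    if scale is None:
        req = 0.0
        for u, w in g.edges:
            bu, bw = blocks[u], blocks[w]
            r0 = mixed_bond_length(
                bu.beads[bu.binder_indices[0]], bw.beads[bw.binder_indices[0]]
            )
            d_req = bu.binder_extent() + bw.binder_extent() + r0
            d_cur = np.linalg.norm(pos[u] - pos[w])
            req = max(req, d_req / d_cur)
        scale = req

    sigma_bar = float(
        np.mean([s.sigma for b in blocks.values() for s in b.beads])
    )
    for _ in range(30):
        placement = _place_at_scale(g, blocks, scale)
        if _min_interblock_distance(placement) >= min_clearance * sigma_bar:
            return placement
        scale *= 1.1
    return placement  # best effort; minimisation resolves residual clashes


def _min_interblock_distance(p: Placement) -> float:
    owner = np.array(p.bead_owner)
    d = np.linalg.norm(p.coords[:, None] - p.coords[None, :], axis=-1)
    mask = owner[:, None] != owner[None, :]
    return float(d[mask].min()) if mask.any() else math.inf


def _place_at_scale(
    g: TopologyGraph, blocks: dict[int, BuildingBlock], scale: float
) -> Placement:
    pos = {v.id: scale * np.array(v.position) for v in g.vertices}
    coords_out: list[np.ndarray] = []
    specs: list[BeadSpec] = []
    owner: list[int] = []
    slices: dict[int, tuple[int, int]] = {}
    binder_for_edge: dict[tuple[int, int], int] = {}
    offset = 0
    for v in g.vertices:
        block = blocks[v.id]
        inc = g.incident_edges(v.id)
        targets = []
        for ei in inc:
            u, w = g.edges[ei]
            other = w if u == v.id else u
            d = pos[other] - pos[v.id]
            targets.append(d / np.linalg.norm(d))
        rot, perm = _align_block(block, np.array(targets))
        placed = rot.apply(block.coords) + pos[v.id]
        for k, ei in enumerate(inc):
            binder_for_edge[(v.id, ei)] = offset + block.binder_indices[perm[k]]
        coords_out.append(placed)
        specs.extend(block.beads)
        owner.extend([v.id] * block.n_beads)
        slices[v.id] = (offset, offset + block.n_beads)
        offset += block.n_beads
    return Placement(
        coords=np.concatenate(coords_out),
        bead_specs=specs,
        bead_owner=owner,
        block_slices=slices,
        binder_for_edge=binder_for_edge,
        scale=scale,
    )


def form_bonds_and_terms(
    g: TopologyGraph,
    blocks: dict[int, BuildingBlock],
    placement: Placement,
    torsion_state: str = "on",
    straightness_angles: bool = True,
) -> CageModel:
    """Enumerate every force-field term of the assembled cage.

    Per topology edge: one constructed binder-binder bond; at a ditopic end
    a b-a-c angle term at the block's target; at a polytopic end a
    centre-binder-partner straightness term at 180 degrees.  With
    ``torsion_state='on'`` each ditopic block contributes one (b, a, a, b)
    torsion restricted to 0.
    """
    if torsion_state not in ("on", "off"):
        raise ValueError("torsion_state must be 'on' or 'off'")
    specs = placement.bead_specs
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    torsions: list[TorsionTerm] = []
    block_kind = {vid: blocks[vid].kind for vid in placement.block_slices}

    # internal terms, shifted to global indices
    centre_global: dict[int, int] = {}
    for v in g.vertices:
        start, _ = placement.block_slices[v.id]
        block = blocks[v.id]
        centre_global[v.id] = start + block.centre_index
        for i, j, r0 in block.bonds:
            bonds.append(BondTerm(start + i, start + j, r0, constructed=False))
        for i, j, k, th in block.angles:
            angles.append(AngleTerm(start + i, start + j, start + k, th))

    # constructed bonds and assembly angle terms
    bond_partner: dict[int, int] = {}
    for ei, (u, w) in enumerate(g.edges):
        bi = placement.binder_for_edge.get((u, ei))
        bj = placement.binder_for_edge.get((w, ei))
        if bi is None or bj is None:
            raise AssemblyError(f"edge {ei} ({u},{w}) has no free binder")
        r0 = mixed_bond_length(specs[bi], specs[bj])
        bonds.append(BondTerm(bi, bj, r0, constructed=True))
        bond_partner[bi] = bj
        bond_partner[bj] = bi
        for end, other in ((bi, bj), (bj, bi)):
            vid = placement.bead_owner[end]
            block = blocks[vid]
            if block.kind == "ditopic":
                assert block.bac_target is not None
                angles.append(AngleTerm(other, end, centre_global[vid], block.bac_target))
            elif straightness_angles:
                angles.append(AngleTerm(centre_global[vid], end, other, 180.0))

    if torsion_state == "on":
        for v in g.vertices:
            block = blocks[v.id]
            if block.kind != "ditopic":
                continue
            start, _ = placement.block_slices[v.id]
            a1 = start + block.binder_indices[0]
            a2 = start + block.binder_indices[1]
            b1 = bond_partner.get(a1)
            b2 = bond_partner.get(a2)
            if b1 is None or b2 is None:
                raise AssemblyError(f"ditopic block at vertex {v.id} not fully bonded")
            torsions.append(TorsionTerm(b1, a1, a2, b2))

    return CageModel(
        topology=g.name,
        coords=placement.coords.copy(),
        bead_specs=list(specs),
        bead_owner=list(placement.bead_owner),
        block_kind=block_kind,
        block_slices=dict(placement.block_slices),
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        torsion_state=torsion_state,
    )


def build_cage(
    g: TopologyGraph,
    blocks_by_arity: dict[int, BuildingBlock],
    torsion_state: str = "on",
    scale: float | None = None,
) -> CageModel:
    """Convenience: one block prototype per arity, assembled on ``g``.

    Every vertex of a given arity receives (a copy of) the same block.
    """
    blocks = {}
    for v in g.vertices:
        if v.arity not in blocks_by_arity:
            raise AssemblyError(
                f"no building block of arity {v.arity} supplied for vertex {v.id}"
            )
        blocks[v.id] = blocks_by_arity[v.arity]
    placement = place_building_blocks(g, blocks, scale=scale)
    return form_bonds_and_terms(g, blocks, placement, torsion_state=torsion_state)
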