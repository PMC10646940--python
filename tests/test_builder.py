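"""Cage assembly: placement, bond formation, term enumeration."""

import networkx as nx
import numpy as np
import pytest

from cgcage import AssemblyError, build_cage, get_topology, make_block
from cgcage.builder import form_bonds_and_terms, place_building_blocks
from conftest import make_cage


def blocks_for(topology, combo):
    arity = {"ditopic": 2, "tritopic": 3, "tetratopic": 4}
    protos = {arity[k]: make_block(k, a) for k, a in combo.items()}
    g = get_topology(topology)
    return g, {v.id: protos[v.arity] for v in g.vertices}


def test_tri4di6_term_counts():
    cage = make_cage("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0})
    assert cage.n_beads == 34  # 4*4 + 6*3
    assert len(cage.constructed_bonds()) == 12
    assert len(cage.intra_block_bonds()) == 24
    bac = [a for a in cage.angles if a.theta0 == 125.0]
    assert len(bac) == 12  # one per constructed bond, at its a end
    # assembly adds one 180-degree centre-binder-partner term per bond too
    n_internal = 6 * 1 + 4 * 3  # ditopic a-c-a + tritopic b-n-b terms
    assert len(cage.angles) == n_internal + 12 + 12
    assert len(cage.torsions) == 6  # one per ditopic block


def test_torsion_state_off_empty():
    cage = make_cage("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0}, "off")
    assert cage.torsions == []


def test_tet6tri8_has_no_ditopic_terms():
    cage = make_cage("Tet6Tri8", {"tritopic": 110.0, "tetratopic": 90.0})
    assert len(cage.constructed_bonds()) == 24
    for bond in cage.constructed_bonds():
        assert cage.bead_specs[bond.i].class_label == "b"
        assert cage.bead_specs[bond.j].class_label == "b"
    assert cage.torsions == []
    # no b-a-c terms: every assembly angle is a 180-degree straightness term
    n_internal = 8 * 3 + 6 * 6
    assert len(cage.angles) == n_internal + 2 * 24


def test_arity_mismatch_names_vertex():
    g = get_topology("Tri4Di6")
    bad = {v.id: make_block("ditopic", 120.0) for v in g.vertices}
    with pytest.raises(AssemblyError, match="vertex 0"):
        place_building_blocks(g, bad)


def test_rebuild_is_deterministic():
    a = make_cage("Tri6Di9", {"ditopic": 130.0, "tritopic": 90.0})
    b = make_cage("Tri6Di9", {"ditopic": 130.0, "tritopic": 90.0})
    assert np.array_equal(a.coords, b.coords)
    assert a.bonds == b.bonds
    assert a.angles == b.angles
    assert a.torsions == b.torsions


def test_every_binder_used_exactly_once():
    for topology, combo in [
        ("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0}),
        ("Tet6Tri8", {"tritopic": 110.0, "tetratopic": 90.0}),
    ]:
        cage = make_cage(topology, combo)
        ends = [b for bond in cage.constructed_bonds() for b in (bond.i, bond.j)]
        assert len(ends) == len(set(ends))
        for bead in ends:
            assert cage.bead_specs[bead].class_label in ("a", "b")


def test_bond_graph_connected_and_all_beads_bonded():
    cage = make_cage("Tet6Di12", {"ditopic": 135.0, "tetratopic": 90.0})
    g = nx.Graph()
    g.add_nodes_from(range(cage.n_beads))
    g.add_edges_from((b.i, b.j) for b in cage.bonds)
    assert nx.is_connected(g)
    assert min(dict(g.degree).values()) >= 1


def test_no_coincident_beads_after_placement():
    for name in ("Tri4_2Di6", "Tet4_2Di8"):
        combo = (
            {"ditopic": 120.0, "tritopic": 100.0}
            if name.startswith("Tri")
            else {"ditopic": 120.0, "tetratopic": 80.0}
        )
        cage = make_cage(name, combo)
        d = np.linalg.norm(cage.coords[:, None] - cage.coords[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0.5


def test_exclusion_exemption_is_two_bond_neighbourhood():
    cage = make_cage("Tri2Di3", {"ditopic": 120.0, "tritopic": 110.0})
    exempt = cage.exclusion_exempt_pairs()
    g = nx.Graph((b.i, b.j) for b in cage.bonds)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    expected = {
        (min(i, j), max(i, j))
        for i, d in lengths.items()
        for j in d
        if i != j
    }
    assert exempt == expected
    pairs = cage.nonexempt_pairs()
    total = cage.n_beads * (cage.n_beads - 1) // 2
    assert len(pairs) + len(exempt) == total


def test_aligned_ditopic_identity_rotation():
    """A ditopic block whose binders already point along its two edges keeps
    its orientation (superposition residual ~ 0)."""
    g = get_topology("Tri2Di3")
    _, blocks = blocks_for("Tri2Di3", {"ditopic": 120.0, "tritopic": 110.0})
    placement = place_building_blocks(g, blocks)
    # equatorial ditopic vertices bind the two poles; binder beads must sit
    # within 90 degrees of their assigned edge directions
    for v in g.vertices:
        if v.arity != 2:
            continue
        start, stop = placement.block_slices[v.id]
        centre = placement.coords[start:stop].mean(axis=0)
        for ei in g.incident_edges(v.id):
            bead = placement.binder_for_edge[(v.id, ei)]
            u, w = g.edges[ei]
            other = w if u == v.id else u
            target = np.array(g.vertex(other).position) * placement.scale - centre
            binder_dir = placement.coords[bead] - centre
            cos = np.dot(target, binder_dir) / (
                np.linalg.norm(target) * np.linalg.norm(binder_dir)
            )
            assert cos > 0  # within 90 degrees


def test_scale_accommodates_block_extent():
    g, blocks = blocks_for("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0})
    placement = place_building_blocks(g, blocks)
    cage = form_bonds_and_terms(g, blocks, placement)
    for bond in cage.constructed_bonds():
        r = np.linalg.norm(cage.coords[bond.i] - cage.coords[bond.j])
        assert r >= bond.r0 - 1e-6
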