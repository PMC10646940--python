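"""Continuous shape measures (CShM) and approximate pore radius.

The continuous shape measure of a point set Q against a reference polyhedron
P is::

    S(Q, P) = 100 * min_{perm, R, s, t}  sum_i |q_i - (s R p_perm(i) + t)|^2
                                         / sum_i |q_i - centroid(Q)|^2

i.e. the smallest residual over vertex relabelling, proper rotation,
isotropic scale and translation, on a 0-100 scale; 0 means the set is
similar to the reference.  After centring and normalising both sets to unit
Frobenius norm the measure reduces to ``100 * (1 - trace(Sigma)^2)`` where
trace(Sigma) is the Kabsch superposition overlap of the best permutation.

Permutation minimisation is exact for n <= 8: candidate relabellings are
pruned with the radius-pairing bound ``trace(Sigma) <= sum_i |q_i|
|p_perm(i)|`` (each inner product is bounded by the product of norms) and
the survivors evaluated by closed-form superposition; an unpruned exhaustive
enumeration is available as an independent check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .builder import CageModel

# ---------------------------------------------------------------------------
# reference polyhedra


@dataclass(frozen=True)
class ReferenceShape:
    """An ideal polyhedron: centred coordinates, unit Frobenius norm."""

    label: str
    coords: np.ndarray

    @property
    def n(self) -> int:
        return len(self.coords)


def _normalise_shape(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, float)
    p = p - p.mean(axis=0)
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        raise ValueError("degenerate (zero-variance) point set")
    return p / norm


def _ref(label: str, points: np.ndarray) -> ReferenceShape:
    return ReferenceShape(label, _normalise_shape(points))


def _ring(n: int, offset: float = 0.0, z: float = 0.0) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n + offset
    return np.stack([np.cos(ang), np.sin(ang), np.full(n, z)], axis=1)


def _trigonal_prism() -> np.ndarray:
    h = math.sqrt(3.0)  # all edges equal for unit circumradius rings
    return np.vstack([_ring(3, z=h / 2), _ring(3, z=-h / 2)])


def _square_antiprism() -> np.ndarray:
    h = math.sqrt(math.sqrt(2.0))
    return np.vstack([_ring(4, z=h / 2), _ring(4, offset=np.pi / 4, z=-h / 2)])


REFERENCE_SHAPES: dict[str, ReferenceShape] = {
    r.label: r
    for r in [
        _ref("TP-3", _ring(3)),
        _ref("SP-4", _ring(4)),
        _ref(
            "T-4",
            np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float),
        ),
        _ref("TPR-6", _trigonal_prism()),
        _ref(
            "OC-6",
            np.array(
                [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
                float,
            ),
        ),
        _ref("CU-8", np.array(list(itertools.product([-1.0, 1.0], repeat=3)))),
        _ref("SAPR-8", _square_antiprism()),
    ]
}


@dataclass
class ShapeMeasureResult:
    measure: float
    permutation: tuple[int, ...]
    rotation: np.ndarray
    scale: float


def _overlap(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray]:
    """Kabsch overlap trace(Sigma) for unit-norm centred P (ref) and Q (data).

    Returns (trace, R) with R the proper rotation maximising sum q_i . R p_i.
    """
    M = P.T @ Q  # 3x3
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    tr = S[0] + S[1] + d * S[2]
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    return float(tr), R


def _cost_of_perm(Pref: np.ndarray, Q: np.ndarray, perm) -> tuple[float, float, np.ndarray]:
    tr, R = _overlap(Pref[list(perm)], Q)
    tr = max(tr, 0.0)
    return 1.0 - tr * tr, tr, R


def _best_perm_exhaustive(Pref: np.ndarray, Q: np.ndarray):
    """Vectorised enumeration of all permutations (independent check path)."""
    n = len(Q)
    perms = np.array(list(itertools.permutations(range(n))))
    M = np.einsum("pni,nj->pij", Pref[perms], Q)
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", U, Vt)))
    tr = S[:, 0] + S[:, 1] + d * S[:, 2]
    best = int(np.argmax(tr))
    perm = tuple(int(v) for v in perms[best])
    cost, trb, R = _cost_of_perm(Pref, Q, perm)
    return cost, perm, R, trb


def _best_perm_pruned(Pref: np.ndarray, Q: np.ndarray):
    """Exact enumeration with radius-pairing pruning.

    The Cauchy-Schwarz bound ``trace(Sigma) <= sum_i |q_i| |p_perm(i)|``
    discards every permutation whose bound cannot beat the identity
    assignment's cost before any superposition is computed; survivors are
    evaluated exactly (batched SVD).
    """
    n = len(Q)
    rq = np.linalg.norm(Q, axis=1)
    rp = np.linalg.norm(Pref, axis=1)
    c_seed, tr_seed, R_seed = _cost_of_perm(Pref, Q, tuple(range(n)))

    perms = np.array(list(itertools.permutations(range(n))))
    ub = (rp[perms] * rq).sum(axis=1)  # per-perm upper bound on trace(Sigma)
    keep = (1.0 - ub * ub) < c_seed + 1e-12
    best = (c_seed, tuple(range(n)), R_seed, tr_seed)
    if keep.any():
        survivors = perms[keep]
        M = np.einsum("pni,nj->pij", Pref[survivors], Q)
        U, S, Vt = np.linalg.svd(M)
        d = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", U, Vt)))
        tr = S[:, 0] + S[:, 1] + d * S[:, 2]
        bi = int(np.argmax(tr))
        if tr[bi] > tr_seed:
            perm = tuple(int(v) for v in survivors[bi])
            cost, trb, R = _cost_of_perm(Pref, Q, perm)
            best = (cost, perm, R, trb)
    return best


def cshm(
    points: np.ndarray,
    ref: ReferenceShape | str,
    method: str = "pruned",
) -> ShapeMeasureResult:
    """Continuous shape measure of ``points`` against a reference shape.

    ``method`` is ``'pruned'`` (branch-and-bound, default) or
    ``'exhaustive'`` (full vectorised enumeration); both are exact and must
    agree.
    """
    if isinstance(ref, str):
        ref = REFERENCE_SHAPES[ref]
    pts = np.asarray(points, float)
    if pts.shape != (ref.n, 3):
        raise ValueError(
            f"point set has shape {pts.shape}, reference {ref.label} needs ({ref.n}, 3)"
        )
    Q = _normalise_shape(pts)
    if method == "exhaustive":
        cost, perm, R, tr = _best_perm_exhaustive(ref.coords, Q)
    elif method == "pruned":
        cost, perm, R, tr = _best_perm_pruned(ref.coords, Q)
    else:
        raise ValueError(f"unknown method {method!r}")
    # optimal isotropic scale on the original (unnormalised) data scale
    data_norm = np.linalg.norm(pts - pts.mean(axis=0))
    scale = tr * data_norm  # |ref| = 1
    measure = float(np.clip(100.0 * cost, 0.0, 100.0))
    # map permutation to data order: perm[i] = reference vertex matched to q_i
    perm_tuple = tuple(int(p) for p in perm)
    return ShapeMeasureResult(measure=measure, permutation=perm_tuple, rotation=R, scale=scale)


# ---------------------------------------------------------------------------
# cage-level analyses

#: which centroid sets are measured against which references, per topology
#: (sets with more than 8 vertices are skipped)
SHAPE_MAP: dict[str, list[tuple[str, str]]] = {
    "Tri2Di3": [("TP-3", "ditopic")],
    "Tet2Di4": [("SP-4", "ditopic")],
    "Tri4Di6": [("T-4", "tritopic"), ("OC-6", "ditopic")],
    "Tri4_2Di6": [("T-4", "tritopic"), ("OC-6", "ditopic")],
    "Tri6Di9": [("TPR-6", "tritopic")],
    "Tri8Di12": [("CU-8", "tritopic")],
    "Tet4_2Di8": [("T-4", "tetratopic"), ("SAPR-8", "ditopic")],
    "Tet6Di12": [("OC-6", "tetratopic")],
    "Tet8Di16": [("SAPR-8", "tetratopic")],
    "Tet12Di24": [],
    "Tet6Tri8": [("OC-6", "tetratopic"), ("CU-8", "tritopic")],
}


def bb_centroids(cage: CageModel, which: str) -> np.ndarray:
    """Unweighted per-block bead centroids for blocks of one kind, cage order."""
    if which not in ("ditopic", "tritopic", "tetratopic"):
        raise ValueError(f"unknown building-block kind {which!r}")
    out = []
    for vid, (start, stop) in cage.block_slices.items():
        if cage.block_kind[vid] == which:
            out.append(cage.coords[start:stop].mean(axis=0))
    if not out:
        raise ValueError(f"cage has no {which} building blocks")
    return np.array(out)


def shape_report(cage: CageModel, topology: str | None = None) -> dict[str, float]:
    """All configured shape measures for a cage's topology (label -> value)."""
    topology = topology or cage.topology
    if topology not in SHAPE_MAP:
        import warnings

        warnings.warn(f"no shape mapping configured for topology {topology!r}")
        return {}
    report = {}
    for label, which in SHAPE_MAP[topology]:
        ref = REFERENCE_SHAPES[label]
        pts = bb_centroids(cage, which)
        if len(pts) != ref.n:
            continue
        report[label] = cshm(pts, ref).measure
    return report


def pore_radius(cage: CageModel) -> float:
    """Centroid-to-nearest-bead-surface distance (Angstrom), floored at 0."""
    if cage.n_beads == 0:
        raise ValueError("empty cage")
    centroid = cage.coords.mean(axis=0)
    d = np.linalg.norm(cage.coords - centroid, axis=1)
    sig = np.array([s.sigma for s in cage.bead_specs])
    return float(max(0.0, np.min(d - sig / 2.0)))
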