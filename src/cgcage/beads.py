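"""Bead classes and parameterised building blocks.

The coarse-grained model uses five bead classes:

``a``  ditopic binder, ``c`` ditopic centre, ``b`` polytopic binder,
``n`` tritopic centre, ``m`` tetratopic centre.

A building block is a small rigid-ish cluster of beads built exactly at its
internal equilibrium geometry (zero internal strain).  The geometry is set by
one target internal angle per block type:

* ditopic (a-c-a): the b-a-c target angle ``theta0`` on both ends defines the
  ligand bite angle, ``theta_bite = 2 * (theta0 - 90)`` (valid when the
  b-a-a-b backbone torsion is restricted to 0).
* tritopic (n + 3 b): the three pairwise b-n-b angles, all equal.
* tetratopic (m + 4 b): the four adjacent b-m-b angles, all equal; the two
  opposite angles follow from the square-pyramidal closure.

All angles are degrees at the interface; bond equilibrium lengths between
unlike beads come from the Lorentz-Berthelot (arithmetic-mean) mixing rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BEAD_CLASSES = ("a", "b", "c", "m", "n")

#: default excluded-volume size (Angstrom) and strength (kJ/mol), all classes
DEFAULT_SIGMA = 1.0
DEFAULT_EPSILON = 10.0
#: default equilibrium bond radius (Angstrom), all classes
DEFAULT_BOND_RADIUS = 2.0


@dataclass(frozen=True)
class BeadSpec:
    """One bead class: equilibrium bond radius and excluded-volume parameters.

    Parameters
    ----------
    class_label:
        One of ``a, b, c, m, n``.
    bond_radius:
        Half of the equilibrium bond length between two beads of this class
        (Angstrom); pairs mix by arithmetic mean.
    sigma:
        Excluded-volume size (Angstrom).
    epsilon:
        Excluded-volume strength (kJ/mol).
    """

    class_label: str
    bond_radius: float = DEFAULT_BOND_RADIUS
    sigma: float = DEFAULT_SIGMA
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.class_label not in BEAD_CLASSES:
            raise ValueError(
                f"unknown bead class {self.class_label!r}; expected one of {BEAD_CLASSES}"
            )
        if self.bond_radius <= 0:
            raise ValueError("bond_radius must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def mixed_bond_length(i: BeadSpec, j: BeadSpec) -> float:
    """Equilibrium bond length r0(i, j) = (r_i + r_j) / 2 (arithmetic mixing)."""
    return 0.5 * (i.bond_radius + j.bond_radius)


def bite_angle(theta0: float) -> float:
    """Ditopic bite angle from the internal b-a-c target angle.

    ``theta_bite = 2 * (theta0 - 90)`` for ``90 <= theta0 <= 180`` degrees.
    """
    if not 90.0 <= theta0 <= 180.0:
        raise ValueError(f"theta0 must be in [90, 180] degrees, got {theta0}")
    return 2.0 * (theta0 - 90.0)


@dataclass(frozen=True)
class DitopicSpec:
    """Linear a-c-a building block with a b-a-c target angle on both ends."""

    target_bac_angle: float
    binder: BeadSpec = field(default_factory=lambda: BeadSpec("a"))
    centre: BeadSpec = field(default_factory=lambda: BeadSpec("c"))

    def __post_init__(self) -> None:
        if not 90.0 <= self.target_bac_angle <= 180.0:
            raise ValueError(
                f"target_bac_angle must be in [90, 180], got {self.target_bac_angle}"
            )
        if self.binder.class_label != "a" or self.centre.class_label != "c":
            raise ValueError("ditopic blocks use binder class 'a' and centre class 'c'")

    @property
    def bite_angle(self) -> float:
        return bite_angle(self.target_bac_angle)


@dataclass(frozen=True)
class TritopicSpec:
    """Pyramidal n + 3 b building block; all three b-n-b angles equal."""

    target_bnb_angle: float
    binder: BeadSpec = field(default_factory=lambda: BeadSpec("b"))
    centre: BeadSpec = field(default_factory=lambda: BeadSpec("n"))

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bnb_angle <= 120.0:
            raise ValueError(
                f"target_bnb_angle must be in (0, 120] (120 = planar), "
                f"got {self.target_bnb_angle}"
            )
        if self.binder.class_label != "b" or self.centre.class_label != "n":
            raise ValueError("tritopic blocks use binder class 'b' and centre class 'n'")


@dataclass(frozen=True)
class TetratopicSpec:
    """Square-pyramidal m + 4 b building block; four equal adjacent b-m-b angles."""

    target_bmb_adjacent_angle: float
    binder: BeadSpec = field(default_factory=lambda: BeadSpec("b"))
    centre: BeadSpec = field(default_factory=lambda: BeadSpec("m"))

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bmb_adjacent_angle <= 90.0:
            raise ValueError(
                f"target_bmb_adjacent_angle must be in (0, 90] (90 = square planar), "
                f"got {self.target_bmb_adjacent_angle}"
            )
        if self.binder.class_label != "b" or self.centre.class_label != "m":
            raise ValueError("tetratopic blocks use binder class 'b' and centre class 'm'")

    @property
    def opposite_angle(self) -> float:
        """Trans b-m-b angle implied by the square-pyramid cone, degrees."""
        theta = math.radians(self.target_bmb_adjacent_angle)
        return math.degrees(2.0 * math.acos(math.sqrt(math.cos(theta))))


@dataclass
class BuildingBlock:
    """A parameterised cluster of beads at its internal equilibrium geometry.

    ``coords`` are local coordinates with the anchor (centre bead) at the
    origin; assembly rigidly rotates and translates them onto a topology
    vertex.  ``bonds`` are (i, j, r0) and ``angles`` (i, j, k, theta0_deg)
    with j the apex.
    """

    kind: str  # 'ditopic' | 'tritopic' | 'tetratopic'
    arity: int
    beads: list[BeadSpec]
    coords: np.ndarray
    binder_indices: list[int]
    centre_index: int
    bonds: list[tuple[int, int, float]]
    angles: list[tuple[int, int, int, float]]
    #: b-a-c target angle stored for assembly time (ditopic only; the b
    #: partner bead does not exist until bonds are formed).
    bac_target: float | None = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def binder_extent(self) -> float:
        """Largest anchor-to-binder distance (Angstrom)."""
        return float(max(np.linalg.norm(self.coords[i]) for i in self.binder_indices))


def measured_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees from a coordinate array."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def _cone_polar_angle_tritopic(theta_deg: float) -> float:
    """Polar angle (rad) placing 3 binders at equal pairwise angle theta.

    Three unit vectors on a cone at polar angle alpha with azimuths 0, 120,
    240 degrees have pairwise cosine (3 cos^2 alpha - 1) / 2; solving for
    alpha gives cos^2 alpha = (2 cos theta + 1) / 3.
    """
    c = math.cos(math.radians(theta_deg))
    val = (2.0 * c + 1.0) / 3.0
    if val < 0.0:
        raise ValueError(f"infeasible tritopic angle {theta_deg} deg (> 120)")
    return math.acos(math.sqrt(val))


def _cone_polar_angle_tetratopic(theta_deg: float) -> float:
    """Polar angle (rad) placing 4 binders with adjacent pairwise angle theta.

    Adjacent azimuths differ by 90 degrees, so the adjacent cosine is
    cos^2 alpha; hence alpha = arccos(sqrt(cos theta)).
    """
    c = math.cos(math.radians(theta_deg))
    if c < 0.0:
        raise ValueError(f"infeasible tetratopic angle {theta_deg} deg (> 90)")
    return math.acos(math.sqrt(c))


def make_ditopic(spec: DitopicSpec) -> BuildingBlock:
    """Build the linear a-c-a block: centre at origin, binders on the x axis."""
    r0 = mixed_bond_length(spec.binder, spec.centre)
    coords = np.array([[-r0, 0.0, 0.0], [0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    return BuildingBlock(
        kind="ditopic",
        arity=2,
        beads=[spec.binder, spec.centre, spec.binder],
        coords=coords,
        binder_indices=[0, 2],
        centre_index=1,
        bonds=[(0, 1, r0), (1, 2, r0)],
        # backbone straightness: the bite-angle picture bends the two b-a-c
        # angles symmetrically against a straight a-c-a backbone
        angles=[(0, 1, 2, 180.0)],
        bac_target=spec.target_bac_angle,
    )


def _cone_block(
    kind: str,
    centre: BeadSpec,
    binder: BeadSpec,
    alpha: float,
    azimuths_deg: tuple[float, ...],
) -> tuple[np.ndarray, list[BeadSpec], list[tuple[int, int, float]]]:
    r0 = mixed_bond_length(centre, binder)
    coords = [np.zeros(3)]
    beads = [centre]
    bonds = []
    for k, az in enumerate(azimuths_deg, start=1):
        phi = math.radians(az)
        coords.append(
            r0
            * np.array(
                [
                    math.sin(alpha) * math.cos(phi),
                    math.sin(alpha) * math.sin(phi),
                    math.cos(alpha),
                ]
            )
        )
        beads.append(binder)
        bonds.append((0, k, r0))
    return np.array(coords), beads, bonds


def make_tritopic(spec: TritopicSpec) -> BuildingBlock:
    theta = spec.target_bnb_angle
    alpha = _cone_polar_angle_tritopic(theta)
    coords, beads, bonds = _cone_block(
        "tritopic", spec.centre, spec.binder, alpha, (0.0, 120.0, 240.0)
    )
    angles = [(1, 0, 2, theta), (2, 0, 3, theta), (1, 0, 3, theta)]
    return BuildingBlock(
        kind="tritopic",
        arity=3,
        beads=beads,
        coords=coords,
        binder_indices=[1, 2, 3],
        centre_index=0,
        bonds=bonds,
        angles=angles,
    )


def make_tetratopic(spec: TetratopicSpec) -> BuildingBlock:
    theta = spec.target_bmb_adjacent_angle
    alpha = _cone_polar_angle_tetratopic(theta)
    coords, beads, bonds = _cone_block(
        "tetratopic", spec.centre, spec.binder, alpha, (0.0, 90.0, 180.0, 270.0)
    )
    opposite = math.degrees(2.0 * alpha)
    angles = [
        (1, 0, 2, theta),
        (2, 0, 3, theta),
        (3, 0, 4, theta),
        (1, 0, 4, theta),
        (1, 0, 3, opposite),
        (2, 0, 4, opposite),
    ]
    return BuildingBlock(
        kind="tetratopic",
        arity=4,
        beads=beads,
        coords=coords,
        binder_indices=[1, 2, 3, 4],
        centre_index=0,
        bonds=bonds,
        angles=angles,
    )


def make_block(kind: str, angle: float, **bead_overrides) -> BuildingBlock:
    """Convenience constructor from a block kind and its target angle."""
    if kind == "ditopic":
        return make_ditopic(DitopicSpec(target_bac_angle=angle, **bead_overrides))
    if kind == "tritopic":
        return make_tritopic(TritopicSpec(target_bnb_angle=angle, **bead_overrides))
    if kind == "tetratopic":
        return make_tetratopic(TetratopicSpec(target_bmb_adjacent_angle=angle, **bead_overrides))
    raise ValueError(f"unknown building-block kind {kind!r}")
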