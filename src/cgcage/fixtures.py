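"""Deterministic fixture generation: default bead sets, a mini angle grid
and two reference cages used across examples and tests.

The fixtures emulate a discretised building-block parameter space at desk
scale: a 3x3 angle grid and two exemplar cages that optimise to stable E_b
(a Tri4Di6 tetrahedron-like cage at tritopic 120 / ditopic 125 degrees and a
Tet6Di12 octahedron-like cage at square-planar tetratopic 90 / ditopic 135
degrees).
"""

from __future__ import annotations

from pathlib import Path

from .beads import make_block
from .builder import CageModel, build_cage
from .config import RunConfig, save_config
from .io import write_structure
from .optimiser import OptimisationResult, optimise_cage
from .phase import AngleGrid
from .topologies import get_topology

#: exemplar phase points known to optimise to stable E_b
REFERENCE_CAGES = (
    ("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0}),
    ("Tet6Di12", {"ditopic": 135.0, "tetratopic": 90.0}),
)

MINI_GRID = AngleGrid(
    ditopic=(115.0, 125.0, 135.0),
    tritopic=(100.0, 110.0, 120.0),
    tetratopic=(70.0, 80.0, 90.0),
    torsion_states=("on",),
)

_ARITY = {"ditopic": 2, "tritopic": 3, "tetratopic": 4}


def reference_cage(
    topology: str, combo: dict[str, float], torsion_state: str = "on"
) -> CageModel:
    g = get_topology(topology)
    blocks = {_ARITY[k]: make_block(k, a) for k, a in combo.items()}
    return build_cage(g, blocks, torsion_state=torsion_state)


def make_fixtures(
    seed: int = 0, outdir: str | Path = "fixtures", optimise: bool = True
) -> dict[str, Path]:
    """Write the default fixture set; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cfg = RunConfig(grid=MINI_GRID, seed=seed)
    cfg_path = outdir / "config.yaml"
    save_config(cfg, cfg_path)
    paths["config"] = cfg_path

    for topology, combo in REFERENCE_CAGES:
        cage = reference_cage(topology, combo)
        result: OptimisationResult | None = None
        if optimise:
            result = optimise_cage(cage, seed=seed)
            cage.coords = result.coords
        xyz = outdir / f"{topology}.xyz"
        write_structure(
            cage,
            xyz,
            e_b=result.e_b if result else None,
            breakdown=result.breakdown if result else None,
            properties={"combo": combo, "seed": seed},
        )
        paths[topology] = xyz
    return paths
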