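"""Multi-step conformer search for one cage model.

The sequence is designed to escape the poor local minima of the raw
construction geometry:

1. constrained minimisation with intra-building-block bonds held fixed
   (relaxes the newly constructed bonds first),
2. full minimisation,
3. stochastic dynamics under softened bond/angle potentials,
4. full minimisation of every dynamics frame,
5. outward shift of all beads away from the cage centroid by each configured
   factor (an anti-collapse restart),
6. full minimisation of each shifted start,
7. tight final minimisation of the best candidate.

The reported stability score is the energy per building block,
``E_b = E_total / n_building_blocks``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .builder import CageModel
from .forcefield import (
    CompiledCage,
    EnergyBreakdown,
    ForceFieldParams,
    _minimise_compiled,
    constrained_minimise,
    energy_and_gradient,
    soft_dynamics,
)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the conformer search."""

    shift_factors: tuple[float, ...] = (1.25, 1.5, 2.0)
    md_steps: int = 5000
    md_frames: int = 10
    kBT: float = 2.5  # kJ/mol
    md_dt: float = 0.005
    friction: float = 1.0
    tol: float = 1e-6  # gradient-norm tolerance, steps 1-6
    final_tol: float = 1e-8  # step 7
    max_iter: int = 2000


@dataclass
class OptimisationResult:
    coords: np.ndarray
    breakdown: EnergyBreakdown
    e_b: float
    converged: bool
    trace: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0


def energy_per_bb(breakdown: EnergyBreakdown, n_bbs: int) -> float:
    """E_b = E_total / number of building blocks."""
    if n_bbs < 1:
        raise ValueError("n_bbs must be >= 1")
    return breakdown.total / n_bbs


def optimise_cage(
    cage: CageModel,
    params: ForceFieldParams | None = None,
    search: SearchConfig | None = None,
    seed: int = 0,
) -> OptimisationResult:
    """Run the full conformer search; returns the lowest-energy candidate."""
    params = params or ForceFieldParams()
    search = search or SearchConfig()
    cc = CompiledCage(cage, params)
    trace: list[tuple[str, float]] = []
    candidates: list[tuple[float, np.ndarray, bool]] = []

    def add(label: str, coords: np.ndarray, converged: bool) -> None:
        bd, _ = energy_and_gradient(coords, cc)
        trace.append((label, bd.total))
        candidates.append((bd.total, coords, converged))

    # 1: constrained minimisation, intra-block bonds frozen
    r1 = constrained_minimise(cage, params, tol=search.tol, max_iter=search.max_iter)
    add("constrained", r1.coords, r1.converged)

    # 2: full minimisation
    r2 = _minimise_compiled(r1.coords, cc, tol=search.tol, max_iter=search.max_iter)
    add("minimise", r2.coords, r2.converged)

    # 3-4: softened dynamics, then minimise every frame
    frames = soft_dynamics(
        cage,
        params,
        kBT=search.kBT,
        n_steps=search.md_steps,
        n_frames=search.md_frames,
        seed=seed,
        dt=search.md_dt,
        friction=search.friction,
        coords=r2.coords,
    )
    for fi, frame in enumerate(frames):
        rf = _minimise_compiled(frame, cc, tol=search.tol, max_iter=search.max_iter)
        add(f"md_frame_{fi}", rf.coords, rf.converged)

    # 5-6: outward centroid shifts of the best-so-far, minimised
    best_e, best_x, _ = min(candidates, key=lambda c: c[0])
    centroid = best_x.reshape(-1, 3).mean(axis=0)
    for factor in search.shift_factors:
        shifted = centroid + factor * (best_x.reshape(-1, 3) - centroid)
        rs = _minimise_compiled(shifted, cc, tol=search.tol, max_iter=search.max_iter)
        add(f"shift_{factor}", rs.coords, rs.converged)

    # 7: tight final minimisation of the overall best
    _, best_x, _ = min(candidates, key=lambda c: c[0])
    r7 = _minimise_compiled(best_x, cc, tol=search.final_tol, max_iter=search.max_iter)
    add("final", r7.coords, r7.converged)

    e, x, _ = min(candidates, key=lambda c: c[0])
    bd, g = energy_and_gradient(x, cc)
    # converged when the RMS gradient component is below the step-1-6 tolerance
    conv = float(np.linalg.norm(g)) / math.sqrt(g.size) < search.tol
    return OptimisationResult(
        coords=x.reshape(-1, 3),
        breakdown=bd,
        e_b=energy_per_bb(bd, cage.n_building_blocks),
        converged=conv,
        trace=trace,
        seed=seed,
    )
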