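"""Angle-grid scans, self-sorting classification and accessible topology maps.

A *combo* is one choice of building-block target angles (and torsion state).
Scanning optimises every (topology, combo, torsion state) tuple and records
the energy per building block, E_b.  A structure is deemed accessible
(stable) when E_b falls at or below a threshold — 0.3 kJ/mol by default, a
model-dependent choice exposed as a parameter.  Per combo the self-sorting
outcome is *unstable* (no stable topology), *selective* (exactly one) or
*mixed* (several).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beads import make_block
from .builder import AssemblyError, build_cage
from .forcefield import ForceFieldParams
from .optimiser import OptimisationResult, SearchConfig, optimise_cage
from .topologies import get_topology

logger = logging.getLogger(__name__)

#: default accessibility threshold on E_b (kJ/mol); model dependent
DEFAULT_THRESHOLD = 0.3

_KIND_BY_ARITY = {2: "ditopic", 3: "tritopic", 4: "tetratopic"}


def _span(lo: float, hi: float, step: float) -> tuple[float, ...]:
    return tuple(np.arange(lo, hi + step / 2, step, dtype=float).tolist())


@dataclass(frozen=True)
class AngleGrid:
    """Discretised building-block angle space (degrees)."""

    ditopic: tuple[float, ...] = _span(90, 180, 5)
    tritopic: tuple[float, ...] = _span(50, 120, 10)
    tetratopic: tuple[float, ...] = _span(50, 90, 10)
    torsion_states: tuple[str, ...] = ("on",)

    def angles_for(self, kind: str) -> tuple[float, ...]:
        return getattr(self, kind)


@dataclass
class PhasePointResult:
    topology: str
    combo: dict[str, float]  # kind -> target angle (degrees)
    torsion_state: str
    e_b: float
    stable: bool
    n_building_blocks: int
    seed: int
    result: OptimisationResult | None = None
    shape: dict[str, float] | None = None
    pore_radius: float | None = None
    e_b_spread: float = 0.0

    def combo_key(self) -> tuple[tuple[str, float], ...]:
        return tuple(sorted(self.combo.items()))


@dataclass
class SelfSortOutcome:
    combo: dict[str, float]
    torsion_state: str
    outcome: str  # 'unstable' | 'selective' | 'mixed'
    stable_topologies: tuple[str, ...]
    smallest_stable: str | None


def _point_seed(base_seed: int, topology: str, combo: dict[str, float], torsion: str) -> int:
    """Content-derived seed: stable under evaluation-order changes."""
    key = f"{topology}|{sorted(combo.items())}|{torsion}|{base_seed}"
    return zlib.crc32(key.encode()) % (2**31)


def _required_kinds(topology: str) -> list[str]:
    g = get_topology(topology)
    return sorted({_KIND_BY_ARITY[v.arity] for v in g.vertices})


def evaluate_point(
    topology: str,
    combo: dict[str, float],
    torsion_state: str = "on",
    params: ForceFieldParams | None = None,
    search: SearchConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    repeats: int = 1,
    with_shape: bool = False,
) -> PhasePointResult:
    """Build and optimise one (topology, combo, torsion state) phase point."""
    g = get_topology(topology)
    blocks = {
        {"ditopic": 2, "tritopic": 3, "tetratopic": 4}[kind]: make_block(kind, angle)
        for kind, angle in combo.items()
    }
    cage = build_cage(g, blocks, torsion_state=torsion_state)
    pseed = _point_seed(seed, topology, combo, torsion_state)
    results = [
        optimise_cage(cage, params=params, search=search, seed=(pseed + r) % (2**31))
        for r in range(max(repeats, 1))
    ]
    best = min(results, key=lambda r: r.e_b)
    spread = max(r.e_b for r in results) - min(r.e_b for r in results)
    out = PhasePointResult(
        topology=topology,
        combo=dict(combo),
        torsion_state=torsion_state,
        e_b=best.e_b,
        stable=best.e_b <= threshold,
        n_building_blocks=g.n_building_blocks,
        seed=pseed,
        result=best,
        e_b_spread=spread,
    )
    if with_shape:
        from .builder import CageModel
        from .shape import pore_radius as _pore, shape_report

        optimised = CageModel(
            topology=cage.topology,
            coords=best.coords,
            bead_specs=cage.bead_specs,
            bead_owner=cage.bead_owner,
            block_kind=cage.block_kind,
            block_slices=cage.block_slices,
            bonds=cage.bonds,
            angles=cage.angles,
            torsions=cage.torsions,
            torsion_state=cage.torsion_state,
        )
        out.shape = shape_report(optimised)
        out.pore_radius = _pore(optimised)
    return out


def scan(
    topologies: list[str],
    grid: AngleGrid | None = None,
    params: ForceFieldParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    search: SearchConfig | None = None,
    repeats: int = 1,
    with_shape: bool = False,
    cache: dict | None = None,
) -> list[PhasePointResult]:
    """One optimised result per (topology, combo, torsion state).

    Combos are restricted to the block kinds each topology needs; infeasible
    pairings are skipped with a warning.  ``cache`` (optional dict) makes the
    scan resumable: results are keyed by the full point tuple.
    """
    grid = grid or AngleGrid()
    out: list[PhasePointResult] = []
    for topology in topologies:
        kinds = _required_kinds(topology)
        axes = [grid.angles_for(k) for k in kinds]
        if any(len(ax) == 0 for ax in axes):
            logger.warning("empty grid for topology %s; skipped", topology)
            continue
        combos: list[dict[str, float]] = []
        for idx in np.ndindex(*[len(ax) for ax in axes]):
            combos.append({k: float(axes[ki][idx[ki]]) for ki, k in enumerate(kinds)})
        for torsion in grid.torsion_states:
            for combo in combos:
                key = (topology, tuple(sorted(combo.items())), torsion)
                if cache is not None and key in cache:
                    out.append(cache[key])
                    continue
                try:
                    r = evaluate_point(
                        topology,
                        combo,
                        torsion_state=torsion,
                        params=params,
                        search=search,
                        threshold=threshold,
                        seed=seed,
                        repeats=repeats,
                        with_shape=with_shape,
                    )
                except AssemblyError as err:
                    logger.warning(
                        "skipping infeasible point %s %s %s: %s", topology, combo, torsion, err
                    )
                    continue
                if cache is not None:
                    cache[key] = r
                out.append(r)
    return out


def classify(
    results: list[PhasePointResult], threshold: float = DEFAULT_THRESHOLD
) -> list[SelfSortOutcome]:
    """Self-sorting outcome per (combo, torsion state) across topologies."""
    groups: dict[tuple, list[PhasePointResult]] = {}
    for r in results:
        groups.setdefault((r.combo_key(), r.torsion_state), []).append(r)
    outcomes = []
    for (ckey, torsion), pts in sorted(groups.items()):
        stable = sorted(
            {(p.n_building_blocks, p.topology) for p in pts if p.e_b <= threshold}
        )
        names = tuple(name for _, name in stable)
        if not names:
            outcome = "unstable"
        elif len(names) == 1:
            outcome = "selective"
        else:
            outcome = "mixed"
        outcomes.append(
            SelfSortOutcome(
                combo=dict(ckey),
                torsion_state=torsion,
                outcome=outcome,
                stable_topologies=names,
                smallest_stable=stable[0][1] if stable else None,
            )
        )
    return outcomes


def _family_of(topology: str) -> str | None:
    arities = {v.arity for v in get_topology(topology).vertices}
    if arities == {2, 3}:
        return "3C"
    if arities == {2, 4}:
        return "4C"
    return None


def percent_selected(
    results: list[PhasePointResult],
    thresholds: list[float],
    family: str,
    torsion_state: str = "on",
) -> pd.DataFrame:
    """Percentage of combos with exactly one stable topology vs threshold.

    ``family`` is '3C' (ditopic + tritopic topologies) or '4C' (ditopic +
    tetratopic).
    """
    if family not in ("3C", "4C"):
        raise ValueError("family must be '3C' or '4C'")
    pts = [
        r
        for r in results
        if r.torsion_state == torsion_state and _family_of(r.topology) == family
    ]
    combos = {r.combo_key() for r in pts}
    rows = []
    for t in thresholds:
        n_sel = 0
        for ck in combos:
            stable = {r.topology for r in pts if r.combo_key() == ck and r.e_b <= t}
            if len(stable) == 1:
                n_sel += 1
        pct = 100.0 * n_sel / len(combos) if combos else 0.0
        rows.append({"threshold": t, "percent_selected": pct})
    return pd.DataFrame(rows)


def accessible_map(
    outcomes: list[SelfSortOutcome],
    grid: AngleGrid | None = None,
) -> pd.DataFrame:
    """Tabulate outcomes over the two combo angles (accessible topology map).

    One row per grid point with the stable-topology set, outcome label and
    smallest stable topology; grid points absent from ``outcomes`` (when a
    grid is given) are filled with outcome='unknown'.
    """
    rows = []
    seen = set()
    kinds: tuple[str, ...] = ()
    for o in outcomes:
        items = sorted(o.combo.items())
        kinds = tuple(k for k, _ in items)
        key = tuple(v for _, v in items) + (o.torsion_state,)
        seen.add(key)
        row = {f"angle_{k}": v for k, v in items}
        row.update(
            torsion_state=o.torsion_state,
            outcome=o.outcome,
            stable_set="|".join(o.stable_topologies),
            smallest_stable=o.smallest_stable or "",
        )
        rows.append(row)
    if grid is not None and len(kinds) == 2:
        states = {o.torsion_state for o in outcomes}
        for torsion in states:
            for a in grid.angles_for(kinds[0]):
                for b in grid.angles_for(kinds[1]):
                    if (a, b, torsion) not in seen:
                        rows.append(
                            {
                                f"angle_{kinds[0]}": a,
                                f"angle_{kinds[1]}": b,
                                "torsion_state": torsion,
                                "outcome": "unknown",
                                "stable_set": "",
                                "smallest_stable": "",
                            }
                        )
    df = pd.DataFrame(rows)
    return df.sort_values(list(df.columns[:3])).reset_index(drop=True)


def proportion_accessible(
    results: list[PhasePointResult],
    topology: str,
    threshold: float = DEFAULT_THRESHOLD,
    torsion_state: str = "on",
) -> float:
    """Fraction of grid points where ``topology`` is stable."""
    pts = [r for r in results if r.topology == topology and r.torsion_state == torsion_state]
    if not pts:
        return 0.0
    return sum(r.e_b <= threshold for r in pts) / len(pts)


def results_table(results: list[PhasePointResult]) -> pd.DataFrame:
    """Flat CSV-ready table of scan results."""
    rows = []
    for r in results:
        row = {
            "topology": r.topology,
            "family": _family_of(r.topology) or "other",
            "torsion_state": r.torsion_state,
            "ditopic_angle": r.combo.get("ditopic", np.nan),
            "polytopic_angle": r.combo.get("tritopic", r.combo.get("tetratopic", np.nan)),
            "E_b": r.e_b,
            "stable": r.stable,
            "outcome": "",
            "smallest_stable": "",
            "seed": r.seed,
        }
        rows.append(row)
    return pd.DataFrame(rows)
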