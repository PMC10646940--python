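"""Structure I/O: XYZ files with a JSON term-list sidecar.

Bead models have no bond orders or elements, so structures are written as
plain XYZ (coordinates in Angstrom) with bead classes mapped to placeholder
elements, and the full term lists (bonds, angles, torsions) plus properties
travel in a JSON sidecar next to the XYZ file.  An XYZ without its sidecar
can still be read for shape/pore analysis but refuses energy evaluation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .beads import BeadSpec
from .builder import AngleTerm, BondTerm, CageModel, TorsionTerm
from .forcefield import EnergyBreakdown

#: default bead-class -> element mapping for XYZ output
ELEMENT_MAP = {"a": "C", "b": "O", "c": "N", "m": "Pd", "n": "Fe"}


class ParseError(ValueError):
    pass


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_structure(
    cage: CageModel,
    path: str | Path,
    e_b: float | None = None,
    breakdown: EnergyBreakdown | None = None,
    properties: dict | None = None,
    element_map: dict[str, str] | None = None,
) -> Path:
    """Write an XYZ file plus JSON sidecar; returns the XYZ path."""
    path = Path(path)
    emap = element_map or ELEMENT_MAP
    comment = f"topology={cage.topology} torsion={cage.torsion_state}"
    if e_b is not None:
        comment += f" E_b={e_b:.6f}"
    lines = [str(cage.n_beads), comment]
    for spec, xyz in zip(cage.bead_specs, cage.coords):
        lines.append(
            f"{emap[spec.class_label]:<2s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}"
        )
    path.write_text("\n".join(lines) + "\n")

    doc = {
        "topology": cage.topology,
        "torsion_state": cage.torsion_state,
        "element_map": emap,
        "beads": [
            {
                "class": s.class_label,
                "bond_radius": s.bond_radius,
                "sigma": s.sigma,
                "epsilon": s.epsilon,
                "vertex": int(v),
            }
            for s, v in zip(cage.bead_specs, cage.bead_owner)
        ],
        "block_kind": {str(k): v for k, v in cage.block_kind.items()},
        "block_slices": {str(k): list(v) for k, v in cage.block_slices.items()},
        "bonds": [[b.i, b.j, b.r0, bool(b.constructed)] for b in cage.bonds],
        "angles": [[a.i, a.j, a.k, a.theta0] for a in cage.angles],
        "torsions": [[t.i, t.j, t.k, t.l, t.phi0, t.p] for t in cage.torsions],
        "properties": dict(properties or {}),
    }
    if e_b is not None:
        doc["properties"]["E_b"] = e_b
    if breakdown is not None:
        doc["properties"]["energy"] = breakdown.as_dict()
    sidecar_path(path).write_text(json.dumps(doc, indent=1))
    return path


def _read_xyz(path: Path) -> tuple[list[str], np.ndarray, str]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: truncated: expected {n} atom lines")
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {ln}: expected 'element x y z'")
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise ParseError(f"{path}: line {ln}: non-numeric coordinate") from None
        elements.append(parts[0])
    return elements, np.array(coords), comment


def read_structure(path: str | Path) -> CageModel:
    """Reconstruct a cage model from XYZ (+ sidecar if present).

    Without the sidecar the model carries coordinates only (term lists
    empty, ``torsion_state='unknown'``); shape and pore analyses work but
    energy evaluation raises.
    """
    path = Path(path)
    elements, coords, comment = _read_xyz(path)
    side = sidecar_path(path)
    if not side.exists():
        inv_map = {v: k for k, v in ELEMENT_MAP.items()}
        specs = [BeadSpec(inv_map.get(el, "a")) for el in elements]
        topo = "unknown"
        for tok in comment.split():
            if tok.startswith("topology="):
                topo = tok.split("=", 1)[1]
        return CageModel(
            topology=topo,
            coords=coords,
            bead_specs=specs,
            bead_owner=list(range(len(specs))),
            block_kind={},
            block_slices={i: (i, i + 1) for i in range(len(specs))},
            torsion_state="unknown",
        )
    doc = json.loads(side.read_text())
    if len(doc["beads"]) != len(coords):
        raise ParseError(
            f"{side}: sidecar lists {len(doc['beads'])} beads, XYZ has {len(coords)}"
        )
    specs = [
        BeadSpec(b["class"], b["bond_radius"], b["sigma"], b["epsilon"])
        for b in doc["beads"]
    ]
    return CageModel(
        topology=doc["topology"],
        coords=coords,
        bead_specs=specs,
        bead_owner=[int(b["vertex"]) for b in doc["beads"]],
        block_kind={int(k): v for k, v in doc["block_kind"].items()},
        block_slices={int(k): tuple(v) for k, v in doc["block_slices"].items()},
        bonds=[BondTerm(int(i), int(j), float(r0), bool(c)) for i, j, r0, c in doc["bonds"]],
        angles=[AngleTerm(int(i), int(j), int(k), float(t)) for i, j, k, t in doc["angles"]],
        torsions=[
            TorsionTerm(int(i), int(j), int(k), int(l), float(phi0), int(p))
            for i, j, k, l, phi0, p in doc["torsions"]
        ],
        torsion_state=doc["torsion_state"],
    )


def has_terms(cage: CageModel) -> bool:
    return bool(cage.bonds)
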