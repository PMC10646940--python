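"""Run configuration: one YAML document driving the whole pipeline.

Every field has a documented default equal to the library default, so an
empty config file is a valid complete configuration; the file round-trips
losslessly through :func:`load_config` / :func:`save_config`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beads import DEFAULT_BOND_RADIUS, DEFAULT_EPSILON, DEFAULT_SIGMA
from .forcefield import ForceFieldParams
from .optimiser import SearchConfig
from .phase import DEFAULT_THRESHOLD, AngleGrid

logger = logging.getLogger(__name__)


@dataclass
class BeadDefaults:
    """Per-class bead parameters; identical defaults for every class."""

    bond_radius: dict[str, float] = field(
        default_factory=lambda: {c: DEFAULT_BOND_RADIUS for c in "abcmn"}
    )
    sigma: dict[str, float] = field(
        default_factory=lambda: {c: DEFAULT_SIGMA for c in "abcmn"}
    )
    epsilon: dict[str, float] = field(
        default_factory=lambda: {c: DEFAULT_EPSILON for c in "abcmn"}
    )


@dataclass
class RunConfig:
    beads: BeadDefaults = field(default_factory=BeadDefaults)
    grid: AngleGrid = field(default_factory=AngleGrid)
    topologies: list[str] = field(default_factory=list)  # empty = all registered
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    search: SearchConfig = field(default_factory=SearchConfig)
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    output_dir: str = "cgcage_out"

    def log_defaults(self) -> None:
        """Record every parameter in effect (auditable parameterisation)."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_config(path: str | Path | None = None) -> RunConfig:
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "beads" in doc:
        cfg.beads = BeadDefaults(**doc["beads"])
    if "grid" in doc:
        g = doc["grid"]
        cfg.grid = AngleGrid(
            ditopic=tuple(g.get("ditopic", AngleGrid().ditopic)),
            tritopic=tuple(g.get("tritopic", AngleGrid().tritopic)),
            tetratopic=tuple(g.get("tetratopic", AngleGrid().tetratopic)),
            torsion_states=tuple(g.get("torsion_states", ("on",))),
        )
    if "forcefield" in doc:
        cfg.forcefield = ForceFieldParams(**doc["forcefield"])
    if "search" in doc:
        s = dict(doc["search"])
        if "shift_factors" in s:
            s["shift_factors"] = tuple(s["shift_factors"])
        cfg.search = SearchConfig(**s)
    for key in ("topologies", "threshold", "seed", "output_dir"):
        if key in doc:
            setattr(cfg, key, doc[key])
    return cfg
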