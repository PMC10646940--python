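"""The coarse-grained force field and its minimisation/dynamics primitives.

Potential energy::

    E = E_bond + E_angle + E_torsion + E_excl_vol

with harmonic bond and angle terms (1/2 convention, angles in radians),
a cosine torsion ``k (1 + cos(p*phi - phi0))`` and a purely repulsive
12th-power excluded-volume term ``sqrt(eps_i eps_j) (sigma_ij / r)^12``
(arithmetic-mean sigma), truncated and shifted to zero at ``cutoff_mult *
sigma_ij``.  Excluded volume is switched off for bead pairs separated by two
or fewer bonds.  The purely repulsive form mimics a good solvent: overlap is
penalised, there is no attractive well.

Default constants (matching common molecular-mechanics scales):
``k_bond = 1e5 kJ/mol/nm^2 = 1e3 kJ/mol/A^2``, ``k_angle = 1e2 kJ/mol/rad^2``,
``k_torsion = 50 kJ/mol``, ``p = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .builder import CageModel

_R_GUARD = 0.05  # Angstrom floor on pair distances inside the repulsion


@dataclass(frozen=True)
class ForceFieldParams:
    k_bond: float = 1.0e3  # kJ/mol/A^2  (= 1e5 kJ/mol/nm^2)
    k_angle: float = 1.0e2  # kJ/mol/rad^2
    k_torsion: float = 50.0  # kJ/mol
    p: int = 1
    cutoff_mult: float = 3.0  # excluded-volume cutoff in units of sigma_ij
    soften_bond: float = 0.1  # k_bond multiplier during softened dynamics
    soften_angle: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k_bond", "k_angle", "k_torsion", "cutoff_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EnergyBreakdown:
    bond: float
    angle: float
    torsion: float
    excl_vol: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.torsion + self.excl_vol

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "torsion": self.torsion,
            "excluded_volume": self.excl_vol,
            "total": self.total,
        }


class CompiledCage:
    """Immutable index/parameter arrays for fast term evaluation."""

    def __init__(self, cage: CageModel, params: ForceFieldParams):
        self.n = cage.n_beads
        self.params = params
        b = cage.bonds
        self.bond_i = np.array([t.i for t in b], dtype=np.intp)
        self.bond_j = np.array([t.j for t in b], dtype=np.intp)
        self.bond_r0 = np.array([t.r0 for t in b])
        self.bond_constructed = np.array([t.constructed for t in b], dtype=bool)
        a = cage.angles
        self.ang_i = np.array([t.i for t in a], dtype=np.intp)
        self.ang_j = np.array([t.j for t in a], dtype=np.intp)
        self.ang_k = np.array([t.k for t in a], dtype=np.intp)
        self.ang_t0 = np.radians([t.theta0 for t in a])
        t = cage.torsions
        self.tor_i = np.array([q.i for q in t], dtype=np.intp)
        self.tor_j = np.array([q.j for q in t], dtype=np.intp)
        self.tor_k = np.array([q.k for q in t], dtype=np.intp)
        self.tor_l = np.array([q.l for q in t], dtype=np.intp)
        self.tor_phi0 = np.radians([q.phi0 for q in t])
        self.tor_p = np.array([q.p for q in t], dtype=float)
        pairs = cage.nonexempt_pairs()
        self.nb_i = pairs[:, 0]
        self.nb_j = pairs[:, 1]
        sig = np.array([s.sigma for s in cage.bead_specs])
        eps = np.array([s.epsilon for s in cage.bead_specs])
        self.nb_sigma = 0.5 * (sig[self.nb_i] + sig[self.nb_j])
        self.nb_eps = np.sqrt(eps[self.nb_i] * eps[self.nb_j])
        self.nb_rc = params.cutoff_mult * self.nb_sigma
        with np.errstate(divide="ignore"):
            self.nb_shift = np.where(
                self.nb_rc > 0, self.nb_eps * (self.nb_sigma / self.nb_rc) ** 12, 0.0
            )
        # restraint slots (constrained minimisation); empty by default
        self.res_i = np.empty(0, dtype=np.intp)
        self.res_j = np.empty(0, dtype=np.intp)
        self.res_r0 = np.empty(0)
        self.res_k = np.empty(0)

    def with_restraints(self, i, j, r0, k) -> "CompiledCage":
        import copy

        out = copy.copy(self)
        out.res_i = np.asarray(i, dtype=np.intp)
        out.res_j = np.asarray(j, dtype=np.intp)
        out.res_r0 = np.asarray(r0, dtype=float)
        out.res_k = np.asarray(k, dtype=float)
        return out


def _accumulate(g: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    """g[idx] += contrib with repeated indices, via bincount (fast path)."""
    n = g.shape[0]
    for dim in range(3):
        g[:, dim] += np.bincount(idx, weights=contrib[:, dim], minlength=n)


def _bond_energy_grad(x, i, j, r0, k):
    d = x[i] - x[j]
    r = np.linalg.norm(d, axis=1)
    dr = r - r0
    if np.isscalar(k):
        e = 0.5 * k * float(dr @ dr)
    else:
        e = 0.5 * float(k @ (dr * dr))
    f = (k * dr / np.maximum(r, 1e-12))[:, None] * d
    g = np.zeros_like(x)
    _accumulate(g, i, f)
    _accumulate(g, j, -f)
    return e, g


def _angle_energy_grad(x, i, j, k_, t0, kc):
    u = x[i] - x[j]
    v = x[k_] - x[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    hu = u / nu[:, None]
    hv = v / nv[:, None]
    c = np.clip(np.sum(hu * hv, axis=1), -1.0, 1.0)
    th = np.arccos(c)
    dt = th - t0
    e = 0.5 * kc * float(dt @ dt)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
    fac = kc * dt / s  # dE/dtheta / sin(theta) guard
    gi = (-fac / nu)[:, None] * (hv - c[:, None] * hu)
    gk = (-fac / nv)[:, None] * (hu - c[:, None] * hv)
    g = np.zeros_like(x)
    _accumulate(g, i, gi)
    _accumulate(g, k_, gk)
    _accumulate(g, j, -(gi + gk))
    return e, g


def _torsion_energy_grad(x, i, j, k_, l, phi0, p, kc):
    b1 = x[j] - x[i]
    b2 = x[k_] - x[j]
    b3 = x[l] - x[k_]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-16)
    n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-16)
    m = np.cross(n1, b2 / nb2[:, None])
    yv = np.sum(m * n2, axis=1)
    xv = np.sum(n1 * n2, axis=1)
    phi = np.arctan2(yv, xv)
    arg = p * phi - phi0
    e = kc * float(np.sum(1.0 + np.cos(arg)))
    dEdphi = -kc * p * np.sin(arg)
    # Blondel-Karplus dihedral derivatives, singularity-free
    gi = (nb2 / n1sq)[:, None] * n1
    gl = (-nb2 / n2sq)[:, None] * n2
    s = np.sum(b1 * b2, axis=1) / np.maximum(nb2 * nb2, 1e-16)
    t = np.sum(b3 * b2, axis=1) / np.maximum(nb2 * nb2, 1e-16)
    gj = -(1.0 + s)[:, None] * gi + t[:, None] * gl
    gk = s[:, None] * gi - (1.0 + t)[:, None] * gl
    g = np.zeros_like(x)
    w = dEdphi[:, None]
    _accumulate(g, i, w * gi)
    _accumulate(g, j, w * gj)
    _accumulate(g, k_, w * gk)
    _accumulate(g, l, w * gl)
    return e, g


def _exclvol_energy_grad(x, cc: CompiledCage):
    if len(cc.nb_i) == 0:
        return 0.0, np.zeros_like(x)
    d = x[cc.nb_i] - x[cc.nb_j]
    r = np.linalg.norm(d, axis=1)
    rg = np.maximum(r, _R_GUARD * cc.nb_sigma)
    inside = r < cc.nb_rc
    if not inside.any():
        return 0.0, np.zeros_like(x)
    sr12 = np.where(inside, (cc.nb_sigma / rg) ** 12, 0.0)
    e_terms = np.where(inside, cc.nb_eps * sr12 - cc.nb_shift, 0.0)
    e = float(e_terms.sum())
    dEdr = np.where(inside, -12.0 * cc.nb_eps * sr12 / rg, 0.0)
    # where r hit the guard the energy is flat in r; keep the clamped slope
    f = (dEdr / np.maximum(r, 1e-12))[:, None] * d
    g = np.zeros_like(x)
    _accumulate(g, cc.nb_i, f)
    _accumulate(g, cc.nb_j, -f)
    return e, g


def energy_and_gradient(
    coords: np.ndarray,
    cc: CompiledCage,
    k_bond: float | None = None,
    k_angle: float | None = None,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Total energy breakdown and analytic gradient (kJ/mol, kJ/mol/A)."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    p = cc.params
    kb = p.k_bond if k_bond is None else k_bond
    ka = p.k_angle if k_angle is None else k_angle
    x = coords.reshape(-1, 3)
    e_b, g = _bond_energy_grad(x, cc.bond_i, cc.bond_j, cc.bond_r0, kb)
    if len(cc.ang_i):
        e_a, ga = _angle_energy_grad(x, cc.ang_i, cc.ang_j, cc.ang_k, cc.ang_t0, ka)
        g += ga
    else:
        e_a = 0.0
    if len(cc.tor_i):
        e_t, gt = _torsion_energy_grad(
            x, cc.tor_i, cc.tor_j, cc.tor_k, cc.tor_l, cc.tor_phi0, cc.tor_p, p.k_torsion
        )
        g += gt
    else:
        e_t = 0.0
    e_v, gv = _exclvol_energy_grad(x, cc)
    g += gv
    if len(cc.res_i):
        e_r, gr = _bond_energy_grad(x, cc.res_i, cc.res_j, cc.res_r0, cc.res_k)
        g += gr
        # restraints steer the minimiser but are not part of the force field;
        # they are folded into the bond channel only for the line search
        e_b += e_r
    return EnergyBreakdown(e_b, e_a, e_t, e_v), g


def _require_terms(cage: CageModel) -> None:
    if not cage.bonds:
        raise ValueError(
            "cage model carries no force-field terms (coordinates-only model, "
            "e.g. an XYZ read without its JSON sidecar); energy operations refused"
        )


def energy(cage: CageModel, params: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Force-field energy breakdown of a cage at its current coordinates."""
    _require_terms(cage)
    params = params or ForceFieldParams()
    cc = CompiledCage(cage, params)
    bd, _ = energy_and_gradient(cage.coords, cc)
    return bd


def gradient(cage: CageModel, params: ForceFieldParams | None = None) -> np.ndarray:
    """Analytic gradient of the total energy, shape (n_beads, 3)."""
    _require_terms(cage)
    params = params or ForceFieldParams()
    cc = CompiledCage(cage, params)
    _, g = energy_and_gradient(cage.coords, cc)
    return g


@dataclass
class MinimisationResult:
    coords: np.ndarray
    breakdown: EnergyBreakdown
    converged: bool
    n_iter: int


def _minimise_compiled(
    coords: np.ndarray,
    cc: CompiledCage,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MinimisationResult:
    x0 = coords.reshape(-1).copy()
    e0, _ = energy_and_gradient(x0, cc)

    def fun(x):
        bd, g = energy_and_gradient(x, cc)
        return bd.total, g.reshape(-1)

    opts = {"maxiter": max_iter, "ftol": 1e-14, "gtol": tol * 1e-2}
    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B", options=opts)
    if res.nit == 0 and not res.success:
        # exactly collinear angle terms put the start on a derivative cusp;
        # break the symmetry with a tiny deterministic jitter and retry
        jitter = 1e-4 * np.random.default_rng(0).standard_normal(x0.shape)
        res = _scipy_minimize(fun, x0 + jitter, jac=True, method="L-BFGS-B", options=opts)
    xf = res.x if res.fun <= e0.total else x0
    bd, g = energy_and_gradient(xf, cc)
    converged = float(np.linalg.norm(g)) < tol or bool(res.success)
    return MinimisationResult(
        coords=xf.reshape(-1, 3), breakdown=bd, converged=converged, n_iter=int(res.nit)
    )


def minimise(
    cage: CageModel,
    params: ForceFieldParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MinimisationResult:
    """Gradient-based local minimisation (L-BFGS) of the cage energy."""
    _require_terms(cage)
    params = params or ForceFieldParams()
    cc = CompiledCage(cage, params)
    return _minimise_compiled(cage.coords, cc, tol=tol, max_iter=max_iter)


def constrained_minimise(
    cage: CageModel,
    params: ForceFieldParams | None = None,
    frozen: list[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    k_freeze: float = 1.0e6,
) -> MinimisationResult:
    """Minimise with the listed bonds held at their *current* lengths.

    ``frozen`` indexes into ``cage.bonds``; default freezes every bond not
    formed during cage construction (the intra-building-block bonds).  The
    hold is a stiff harmonic restraint (k_freeze, kJ/mol/A^2).  The returned
    breakdown is the plain force-field energy without restraints.
    """
    _require_terms(cage)
    params = params or ForceFieldParams()
    cc = CompiledCage(cage, params)
    if frozen is None:
        frozen = [idx for idx, b in enumerate(cage.bonds) if not b.constructed]
    if not frozen:
        return _minimise_compiled(cage.coords, cc, tol=tol, max_iter=max_iter)
    for idx in frozen:
        if not 0 <= idx < len(cage.bonds):
            raise IndexError(f"frozen bond index {idx} out of range")
    x = cage.coords
    i = np.array([cage.bonds[idx].i for idx in frozen], dtype=np.intp)
    j = np.array([cage.bonds[idx].j for idx in frozen], dtype=np.intp)
    r_now = np.linalg.norm(x[i] - x[j], axis=1)
    # stiffen the restraint progressively: a cold start at full stiffness can
    # defeat the L-BFGS line search on strained cages
    schedule = [k for k in (1e3, 1e4, 1e5) if k < k_freeze] + [k_freeze]
    coords = cage.coords
    res = None
    for k in schedule:
        ccr = cc.with_restraints(i, j, r_now, np.full(len(frozen), k))
        res = _minimise_compiled(coords, ccr, tol=tol, max_iter=max_iter)
        coords = res.coords
    bd, g = energy_and_gradient(res.coords, cc)
    return MinimisationResult(res.coords, bd, res.converged, res.n_iter)


def soft_dynamics(
    cage: CageModel,
    params: ForceFieldParams | None = None,
    kBT: float = 2.5,
    n_steps: int = 5000,
    n_frames: int = 10,
    seed: int = 0,
    dt: float = 0.005,
    friction: float = 1.0,
    guard: float = 1.0e4,
    coords: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Overdamped Langevin dynamics with softened bond/angle constants.

    Brownian update ``x += -(dt/friction) grad + sqrt(2 kBT dt / friction) xi``
    with per-step displacements capped at 0.25 A for stability; k_bond and
    k_angle are multiplied by the softening factors.  Fully reproducible from
    ``seed``.  Returns ``n_frames`` evenly spaced coordinate frames (the last
    frame is the final state); aborts early (returning the frames collected
    so far) if any coordinate exceeds ``guard``.
    """
    if n_frames > n_steps:
        raise ValueError("n_frames must be <= n_steps")
    _require_terms(cage)
    params = params or ForceFieldParams()
    cc = CompiledCage(cage, params)
    kb = params.k_bond * params.soften_bond
    ka = params.k_angle * params.soften_angle
    rng = np.random.default_rng(seed)
    x = (cage.coords if coords is None else coords).copy()
    frames: list[np.ndarray] = []
    snap_at = set((np.linspace(1, n_steps, n_frames)).astype(int).tolist())
    noise_scale = math.sqrt(2.0 * max(kBT, 0.0) * dt / friction)
    for step in range(1, n_steps + 1):
        _, g = energy_and_gradient(x, cc, k_bond=kb, k_angle=ka)
        dx = -(dt / friction) * g
        if kBT > 0:
            dx = dx + noise_scale * rng.standard_normal(x.shape)
        step_len = np.linalg.norm(dx, axis=1, keepdims=True)
        dx = dx * np.minimum(1.0, 0.25 / np.maximum(step_len, 1e-12))
        x = x + dx
        if np.abs(x).max() > guard:
            break
        if step in snap_at:
            frames.append(x.copy())
    if not frames:
        frames.append(x.copy())
    return frames
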