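"""Overdamped center-based mechanics and the simulation loop.

Cells are particles with axisymmetric-ellipsoid shapes moved by explicit
Euler–Maruyama steps of overdamped dynamics: ``dx = (F/gamma) dt +
noise_amp sqrt(dt) xi`` with thermal noise applied only to living, non-anchored
cells (PROLIF/SPINOUS/GRANULAR). Pairwise contact uses a direction-dependent
ellipsoid radius so flattened corneocytes stack into sheets; the neighbour
search is a uniform spatial hash grid, periodic in x and y.

These force laws are conventional center-based-model choices, reconstructed by
this package; all constants are configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from . import _kernels as K
from .cell_model import Cell, CellState, LifecycleParams, flatten_semi_axes
from .geometry import MembraneSpec, membrane_gap, membrane_height, place_stem_cells

__all__ = ["ForceParams", "RunParams", "SimConfig", "SimState",
           "pairwise_force", "membrane_force", "step", "run",
           "potential_surrogate"]


@dataclass(frozen=True)
class ForceParams:
    k_rep: float = 10.0        # contact repulsion stiffness (force/um)
    k_adh: float = 1.0         # adhesion strength at contact (force)
    adh_range_um: float = 2.0  # adhesion cutoff beyond contact
    k_mem: float = 20.0        # membrane repulsion stiffness
    k_anchor: float = 20.0     # stem anchoring spring stiffness
    gamma: float = 1.0         # drag (normalises force units)
    noise_amp: float = 0.2     # um / sqrt(h)
    dt_h: float = 0.02

    def __post_init__(self) -> None:
        for name in ("k_rep", "k_adh", "adh_range_um", "k_mem", "k_anchor",
                     "gamma", "dt_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"forces.{name} must be > 0")
        if self.noise_amp < 0:
            raise ValueError("forces.noise_amp must be >= 0")


@dataclass(frozen=True)
class RunParams:
    t_total_h: float = 500.0
    snapshot_every_h: float = 25.0
    seed: int = 0
    stem_spacing_um: float = 10.0
    stem_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.t_total_h < 0:
            raise ValueError("run.t_total_h must be >= 0")
        if self.snapshot_every_h <= 0:
            raise ValueError("run.snapshot_every_h must be > 0")


@dataclass(frozen=True)
class SimConfig:
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    lifecycle: LifecycleParams = field(default_factory=LifecycleParams)
    forces: ForceParams = field(default_factory=ForceParams)
    run: RunParams = field(default_factory=RunParams)

    def to_dict(self) -> dict:
        return {"membrane": asdict(self.membrane),
                "lifecycle": asdict(self.lifecycle),
                "forces": asdict(self.forces),
                "run": asdict(self.run)}

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class SimState:
    """All cells (structure-of-arrays) plus time, counters and the RNG.

    Invariants maintained by :func:`step`: unique ids, non-decreasing time and
    counters, and the exact identity ``n_cells == n0 + births - removals``.
    """

    def __init__(self, pos, aa, cc, state, age, ca, anchor, ids,
                 t: float = 0.0, births: int = 0, removals: int = 0,
                 next_id: Optional[int] = None, rng=None,
                 config_hash: str = "", n0: Optional[int] = None):
        self.pos = np.asarray(pos, dtype=np.float64).reshape(-1, 3)
        self.aa = np.asarray(aa, dtype=np.float64)
        self.cc = np.asarray(cc, dtype=np.float64)
        self.state = np.asarray(state, dtype=np.uint8)
        self.age = np.asarray(age, dtype=np.float64)
        self.ca = np.asarray(ca, dtype=np.float64)
        self.anchor = np.asarray(anchor, dtype=np.float64).reshape(-1, 2)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.t = float(t)
        self.births = int(births)
        self.removals = int(removals)
        self.next_id = int(next_id if next_id is not None
                           else (self.ids.max() + 1 if self.ids.size else 0))
        self.rng = rng
        self.config_hash = config_hash
        self.n0 = int(n0 if n0 is not None else self.n_cells)

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @classmethod
    def empty(cls, rng=None, config_hash: str = "") -> "SimState":
        return cls(np.empty((0, 3)), np.empty(0), np.empty(0),
                   np.empty(0, np.uint8), np.empty(0), np.empty(0),
                   np.empty((0, 2)), np.empty(0, np.int64), rng=rng,
                   config_hash=config_hash)

    @classmethod
    def from_cells(cls, cells: List[Cell], rng=None,
                   config_hash: str = "") -> "SimState":
        n = len(cells)
        pos = np.array([c.pos for c in cells]).reshape(n, 3)
        anchor = np.array([(c.anchor if c.anchor is not None else c.pos[:2])
                           for c in cells]).reshape(n, 2)
        return cls(pos,
                   np.array([c.a for c in cells]),
                   np.array([c.c for c in cells]),
                   np.array([int(c.state) for c in cells], np.uint8),
                   np.array([c.age_in_state for c in cells]),
                   np.array([c.ca for c in cells]),
                   anchor,
                   np.array([c.id for c in cells], np.int64),
                   rng=rng, config_hash=config_hash)

    def cells(self) -> List[Cell]:
        """Materialise per-cell dataclass views (copies)."""
        out = []
        for i in range(self.n_cells):
            st = CellState(int(self.state[i]))
            out.append(Cell(
                id=int(self.ids[i]), pos=self.pos[i].copy(),
                a=float(self.aa[i]), c=float(self.cc[i]), state=st,
                age_in_state=float(self.age[i]),
                anchor=self.anchor[i].copy() if st == CellState.STEM else None,
                ca=float(self.ca[i])))
        return out

    def copy(self, with_rng: bool = False) -> "SimState":
        return SimState(self.pos.copy(), self.aa.copy(), self.cc.copy(),
                        self.state.copy(), self.age.copy(), self.ca.copy(),
                        self.anchor.copy(), self.ids.copy(), self.t,
                        self.births, self.removals, self.next_id,
                        self.rng if with_rng else None, self.config_hash,
                        self.n0)

    def counts_by_state(self) -> dict:
        return {s.name: int(np.sum(self.state == int(s))) for s in CellState}


def pairwise_force(ci: Cell, cj: Cell, params: ForceParams,
                   dom_x: float = np.inf, dom_y: float = np.inf) -> np.ndarray:
    """Contact force on cell i from cell j (scalar reference implementation).

    Linear repulsion inside the direction-dependent contact distance R, linear
    adhesion decaying from k_adh at contact to zero at R + adh_range_um.
    Antisymmetric by construction.
    """
    d = ci.pos - cj.pos
    if np.isfinite(dom_x):
        d[0] -= dom_x * np.rint(d[0] / dom_x)
    if np.isfinite(dom_y):
        d[1] -= dom_y * np.rint(d[1] / dom_y)
    d2 = float(d @ d)
    if d2 < 1e-12:
        h = (min(ci.id, cj.id) * 2654435761 + max(ci.id, cj.id) * 40503) & 1023
        ang = 2.0 * np.pi * h / 1024.0
        sgn = 1.0 if ci.id > cj.id else -1.0
        return sgn * params.k_rep * ci.a * np.array([np.cos(ang), np.sin(ang), 0.0])
    dist = np.sqrt(d2)
    uz2 = d[2] * d[2] / d2
    R = (K.directional_radius(ci.a, ci.c, uz2)
         + K.directional_radius(cj.a, cj.c, uz2))
    if dist >= R + params.adh_range_um:
        return np.zeros(3)
    if dist < R:
        mag = params.k_rep * (R - dist)
    else:
        mag = -params.k_adh * (1.0 - (dist - R) / params.adh_range_um)
    return (mag / dist) * d


def membrane_force(cell: Cell, spec: MembraneSpec,
                   params: ForceParams) -> np.ndarray:
    """Membrane contact repulsion plus, for stems, the anchoring spring.

    Contact is assessed on the perpendicular clearance (vertical gap projected
    onto the surface normal), which equals the vertical gap on a flat membrane
    and keeps forces bounded on steep fiber flanks.
    """
    gap, normal = membrane_gap(spec, cell.pos)
    F = np.zeros(3)
    perp = gap * normal[2]
    if perp < cell.c:
        F += params.k_mem * (cell.c - perp) * normal
    if cell.state == CellState.STEM:
        ax, ay = cell.anchor
        az = membrane_height(spec, ax, ay)
        delta = np.array([ax, ay, az]) - cell.pos
        delta[0] -= spec.domain_x_um * np.rint(delta[0] / spec.domain_x_um)
        delta[1] -= spec.domain_y_um * np.rint(delta[1] / spec.domain_y_um)
        F += params.k_anchor * delta
    return F


class DisplacementOverflow(RuntimeError):
    """A cell moved more than half a radius in one step (timestep too large)."""


def _forces(state: SimState, spec: MembraneSpec, fp: ForceParams,
            lp: LifecycleParams):
    return K.compute_forces(
        state.pos, state.aa, state.cc, state.state, state.anchor, state.ids,
        *spec.kernel_args(),
        fp.k_rep, fp.k_adh, fp.adh_range_um, fp.k_mem, fp.k_anchor,
        2.0 * lp.r0_um, int(CellState.STEM), int(CellState.CORNEOCYTE))


def step(state: SimState, spec: MembraneSpec, fp: ForceParams,
         lp: LifecycleParams, rng=None) -> SimState:
    """Advance the simulation by one timestep, in place; returns the state.

    Order of operations (fixed, for reproducibility): forces and motion,
    periodic wrap, stem divisions, differentiation transitions, corneocyte
    flattening, optional calcium relaxation, exposure-gated desquamation,
    removal compaction, time increment. All random draws flow through the
    state's generator in a fixed order with cells in id order.
    """
    if rng is None:
        rng = state.rng
    dt = fp.dt_h
    n = state.n_cells
    guard = 0.5 * lp.r0_um
    if n > 0:
        F, ncount = _forces(state, spec, fp, lp)
        noise = rng.standard_normal((n, 3))
        noisy = (state.state != int(CellState.STEM)) & \
                (state.state != int(CellState.CORNEOCYTE))
        noise_disp = (fp.noise_amp * np.sqrt(dt)) * noise * noisy[:, None]

        # adaptive force substepping: transient pile-ups (births, steep
        # membrane flanks) occasionally produce forces whose full-dt motion
        # would exceed the displacement guard; subdividing the deterministic
        # part and recomputing forces resolves them. Noise is applied once.
        max_force_disp = float(np.max(np.abs(F))) * dt / fp.gamma
        nsub = 1
        while nsub < 8 and max_force_disp / nsub > 0.6 * guard:
            nsub *= 2
        for sub in range(nsub):
            if sub > 0:
                F, _ = _forces(state, spec, fp, lp)
            disp = F * (dt / (nsub * fp.gamma))
            mags = np.max(np.abs(disp), axis=1)
            worst = int(np.argmax(mags))
            if mags[worst] > guard:
                raise DisplacementOverflow(
                    f"cell id {int(state.ids[worst])} moved "
                    f"{mags[worst]:.3f} um in one step at t={state.t:.3f} h "
                    f"(> 0.5*r0 even at dt/{nsub}); reduce dt_h")
            state.pos += disp
            state.pos[:, 0] %= spec.domain_x_um
            state.pos[:, 1] %= spec.domain_y_um
        state.pos += noise_disp
        state.pos[:, 0] %= spec.domain_x_um
        state.pos[:, 1] %= spec.domain_y_um

        # --- divisions -------------------------------------------------
        u_div = rng.random(n)
        stems = state.state == int(CellState.STEM)
        rate_factor = np.ones(n)
        if lp.division_jitter > 0:
            rate_factor += lp.division_jitter * (2.0 * rng.random(n) - 1.0)
        p_div = -np.expm1(-dt * rate_factor / lp.division_period_h)
        firing = stems & (ncount <= lp.crowding_cap) & (u_div < p_div)
        k = int(np.sum(firing))
        if k > 0:
            dirs = rng.standard_normal((k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            dirs[:, 2] = np.abs(dirs[:, 2])
            new_pos = state.pos[firing] + lp.daughter_offset_um * dirs
            new_pos[:, 0] %= spec.domain_x_um
            new_pos[:, 1] %= spec.domain_y_um
            # an upward-hemisphere offset can still put a newborn into (or
            # deep against) a steep membrane; seat it at the clearance where
            # membrane push and anchor-scale forces stay step-size-safe
            perp_eq = lp.r0_um * fp.k_mem / (fp.k_mem + fp.k_anchor)
            for m in range(k):
                gap, normal = membrane_gap(spec, new_pos[m])
                perp = gap * normal[2]
                if perp < perp_eq:
                    new_pos[m] += (perp_eq - perp) * normal
            new_pos[:, 0] %= spec.domain_x_um
            new_pos[:, 1] %= spec.domain_y_um
            new_ids = state.next_id + np.arange(k)
            state.pos = np.vstack([state.pos, new_pos])
            state.aa = np.append(state.aa, np.full(k, lp.r0_um))
            state.cc = np.append(state.cc, np.full(k, lp.r0_um))
            state.state = np.append(
                state.state, np.full(k, int(CellState.PROLIF), np.uint8))
            state.age = np.append(state.age, np.zeros(k))
            state.ca = np.append(state.ca, np.zeros(k))
            state.anchor = np.vstack([state.anchor, new_pos[:, :2]])
            state.ids = np.append(state.ids, new_ids)
            state.age[np.flatnonzero(firing)] = 0.0  # stems reset their clock
            state.next_id += k
            state.births += k
            n = state.n_cells

        # --- differentiation state machine -----------------------------
        gaps = state.pos[:, 2] - membrane_height(
            spec, state.pos[:, 0], state.pos[:, 1])
        u_tr = rng.random(n)
        age_new = state.age + dt

        prolif = state.state == int(CellState.PROLIF)
        to_spinous = prolif & (gaps > lp.diff_height_um)

        spinous = state.state == int(CellState.SPINOUS)
        factor = state.ca if lp.calcium_enabled else 1.0
        p_sg = -np.expm1(-dt * factor / lp.spinous_dur_h)
        to_granular = spinous & (u_tr < p_sg)

        granular = state.state == int(CellState.GRANULAR)
        p_gc = -np.expm1(-dt / lp.granular_dur_h)
        to_corneo = granular & (u_tr < p_gc)

        transitioned = to_spinous | to_granular | to_corneo
        age_new[transitioned] = 0.0
        state.age = age_new
        state.state[to_spinous] = int(CellState.SPINOUS)
        state.state[to_granular] = int(CellState.GRANULAR)
        state.state[to_corneo] = int(CellState.CORNEOCYTE)

        # --- corneocyte flattening (volume-conserving) ------------------
        corneo = state.state == int(CellState.CORNEOCYTE)
        if np.any(corneo):
            q = state.cc[corneo] / state.aa[corneo]
            q = lp.target_aspect + (q - lp.target_aspect) * np.exp(
                -dt / lp.flatten_tau_h)
            a, c = flatten_semi_axes(q, lp.r0_um)
            state.aa[corneo] = a
            state.cc[corneo] = c

        # --- calcium proxy (feature-flagged) ---------------------------
        if lp.calcium_enabled:
            target = np.clip(gaps / (lp.diff_height_um + lp.ca_band_um), 0.0, 1.0)
            state.ca += (target - state.ca) * (-np.expm1(-dt / lp.ca_tau_h))
            np.clip(state.ca, 0.0, 1.0, out=state.ca)

        # --- exposure-gated desquamation -------------------------------
        u_rm = rng.random(n)
        if np.any(corneo):
            exposed = K.exposure_mask(
                state.pos, state.state, spec.domain_x_um, spec.domain_y_um,
                lp.exposure_cone_factor * lp.r0_um, int(CellState.CORNEOCYTE))
            p_rm = -np.expm1(-dt / lp.desquam_dur_h)
            removing = exposed & (u_rm < p_rm)
            k_rm = int(np.sum(removing))
            if k_rm > 0:
                keep = ~removing
                state.pos = state.pos[keep]
                state.aa = state.aa[keep]
                state.cc = state.cc[keep]
                state.state = state.state[keep]
                state.age = state.age[keep]
                state.ca = state.ca[keep]
                state.anchor = state.anchor[keep]
                state.ids = state.ids[keep]
                state.removals += k_rm
    state.t += dt
    return state


def initial_state(config: SimConfig, rng=None) -> SimState:
    """Stems seeded on the membrane, nothing else.

    Anchors are the on-surface seeding points; cell centres start lifted to
    the equilibrium clearance where the membrane push balances the anchor
    spring, so the first step is not dominated by the seating transient.
    """
    if rng is None:
        rng = np.random.default_rng(config.run.seed)
    lp = config.lifecycle
    fp = config.forces
    if config.run.stem_spacing_um < 2 * lp.r0_um:
        raise ValueError("run.stem_spacing_um must be >= 2 * r0")
    anchors = place_stem_cells(config.membrane, config.run.stem_spacing_um,
                               rng, jitter=config.run.stem_jitter)
    perp_eq = lp.r0_um * fp.k_mem / (fp.k_mem + fp.k_anchor)
    pos = anchors.copy()
    for i in range(pos.shape[0]):
        _, normal = membrane_gap(config.membrane, anchors[i])
        pos[i] += perp_eq * normal
    pos[:, 0] %= config.membrane.domain_x_um
    pos[:, 1] %= config.membrane.domain_y_um
    n = pos.shape[0]
    return SimState(
        pos, np.full(n, lp.r0_um), np.full(n, lp.r0_um),
        np.full(n, int(CellState.STEM), np.uint8), np.zeros(n), np.zeros(n),
        anchors[:, :2].copy(), np.arange(n, dtype=np.int64), rng=rng,
        config_hash=config.config_hash)


def _equilibrate(state: SimState, spec: MembraneSpec, fp: ForceParams,
                 lp: LifecycleParams, steps: int = 100) -> None:
    """Deterministic mechanical seating of the initial configuration.

    Relaxes residual seeding overlaps (jittered lattices on steep membranes
    can seed touching stems) with reduced, clamped displacement steps; no
    noise, no lifecycle clocks, and the simulation time does not advance.
    """
    dt = 0.2 * fp.dt_h
    clamp = 0.3 * lp.r0_um
    for _ in range(steps):
        F, _ = _forces(state, spec, fp, lp)
        disp = F * (dt / fp.gamma)
        mags = np.linalg.norm(disp, axis=1)
        big = mags > clamp
        if np.any(big):
            disp[big] *= (clamp / mags[big])[:, None]
        state.pos += disp
        state.pos[:, 0] %= spec.domain_x_um
        state.pos[:, 1] %= spec.domain_y_um


def run(config: SimConfig, progress: bool = False) -> List[SimState]:
    """Run the full simulation, returning snapshot copies every
    ``snapshot_every_h`` hours (the initial state included).

    The initial stem configuration is mechanically equilibrated first; then
    the stochastic loop runs. Fully reproducible from (config, seed); every
    snapshot is checked for NaN/Inf and for the exact birth/removal
    bookkeeping identity.
    """
    state = initial_state(config)
    fp, lp, spec = config.forces, config.lifecycle, config.membrane
    if state.n_cells:
        _equilibrate(state, spec, fp, lp)
    n_steps = int(round(config.run.t_total_h / fp.dt_h))
    every = max(1, int(round(config.run.snapshot_every_h / fp.dt_h)))
    snapshots = [state.copy()]
    for i in range(n_steps):
        step(state, spec, fp, lp)
        if (i + 1) % every == 0 or i + 1 == n_steps:
            snap = state.copy()
            _check_snapshot(snap)
            if not snapshots or snap.t > snapshots[-1].t:
                snapshots.append(snap)
            if progress:  # pragma: no cover - console convenience
                c = snap.counts_by_state()
                print(f"t={snap.t:8.1f} h  N={snap.n_cells:5d}  "
                      f"SC={c['CORNEOCYTE']:5d}  births={snap.births}  "
                      f"removals={snap.removals}")
    return snapshots


def _check_snapshot(s: SimState) -> None:
    if not np.all(np.isfinite(s.pos)):
        raise FloatingPointError(f"non-finite position at t={s.t}")
    if s.n_cells != s.n0 + s.births - s.removals:
        raise AssertionError(
            f"bookkeeping broken at t={s.t}: N={s.n_cells} != "
            f"{s.n0} + {s.births} - {s.removals}")


def potential_surrogate(state: SimState, spec: MembraneSpec,
                        lp: LifecycleParams) -> float:
    """Sum of squared pairwise overlaps plus squared membrane penetrations —
    a Lyapunov-style relaxation diagnostic (brute-force, small states only)."""
    n = state.n_cells
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = state.pos[i] - state.pos[j]
            d[0] -= spec.domain_x_um * np.rint(d[0] / spec.domain_x_um)
            d[1] -= spec.domain_y_um * np.rint(d[1] / spec.domain_y_um)
            d2 = float(d @ d)
            if d2 < 1e-12:
                continue
            uz2 = d[2] * d[2] / d2
            R = (K.directional_radius(state.aa[i], state.cc[i], uz2)
                 + K.directional_radius(state.aa[j], state.cc[j], uz2))
            overlap = R - np.sqrt(d2)
            if overlap > 0:
                total += overlap * overlap
        gap = state.pos[i, 2] - membrane_height(spec, state.pos[i, 0],
                                                state.pos[i, 1])
        pen = state.cc[i] - gap
        if pen > 0:
            total += pen * pen
    return total
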