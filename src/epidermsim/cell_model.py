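"""Keratinocyte lifecycle: a per-cell stochastic state machine.

States progress strictly ``STEM -> (spawns PROLIF) -> SPINOUS -> GRANULAR ->
CORNEOCYTE -> removed``. Stem cells are anchored to the basement membrane and
divide on a memoryless (exponential) clock, suppressed by local crowding.
Proliferative cells differentiate positionally once pushed one cell diameter
clear of the membrane; the spinous and granular residence times are exponential.
Corneocytes flatten exponentially toward a terminal aspect ratio at conserved
volume and desquamate — again on an exponential clock — only while exposed at
the free tissue surface.

The concrete rates and thresholds below are this package's reconstruction of an
epidermal-homeostasis model; every one is overridable through the run config.
The scalar operations here are the reference semantics; the vectorised
simulation loop in :mod:`epidermsim.mechanics` applies the same formulas to
whole arrays.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CellState",
    "Cell",
    "LifecycleParams",
    "attempt_division",
    "update_state",
    "update_flattening",
    "update_calcium",
    "event_probability",
]


class CellState(enum.IntEnum):
    STEM = 0
    PROLIF = 1
    SPINOUS = 2
    GRANULAR = 3
    CORNEOCYTE = 4


LIVING_STATES = (CellState.STEM, CellState.PROLIF, CellState.SPINOUS,
                 CellState.GRANULAR)


@dataclass
class Cell:
    """One keratinocyte: an axisymmetric ellipsoid with semi-axes (a, a, c)."""

    id: int
    pos: np.ndarray
    r0: float = 5.0
    a: float = 5.0
    c: float = 5.0
    state: CellState = CellState.PROLIF
    age_in_state: float = 0.0
    anchor: Optional[np.ndarray] = None
    ca: float = 0.0
    alive: bool = True

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.float64)
        if self.state == CellState.STEM and self.anchor is None:
            raise ValueError("STEM cells must carry an anchor")
        if self.state != CellState.STEM and self.anchor is not None:
            raise ValueError("only STEM cells carry an anchor")

    @property
    def semi_axes(self) -> tuple:
        return (self.a, self.a, self.c)

    @property
    def volume_invariant(self) -> float:
        """a^2 * c, conserved at r0^3 under flattening."""
        return self.a * self.a * self.c


@dataclass(frozen=True)
class LifecycleParams:
    division_period_h: float = 12.0      # mean stem division interval
    division_jitter: float = 0.0         # fractional rate jitter per step
    # Contact inhibition: division is suppressed when more than this many cell
    # centres lie within one cell diameter of the stem. A membrane-seated stem
    # only has its upper half-space available, which holds ~6-8 centres at
    # close packing, so the cap must sit below that for inhibition to engage.
    crowding_cap: int = 4
    diff_height_um: float = 12.0         # clearance triggering PROLIF -> SPINOUS
    spinous_dur_h: float = 24.0
    granular_dur_h: float = 24.0
    flatten_tau_h: float = 6.0
    target_aspect: float = 0.2           # terminal corneocyte c/a
    # mean exposed-corneocyte lifetime; calibrated so shedding balances the
    # crowding-gated production flux at the desk-scale flat steady state
    desquam_dur_h: float = 64.0
    # newborn placement distance from the mother stem; at 7.5 um the initial
    # mother-daughter overlap (2*r0 - offset = 2.5 um) keeps the birth force
    # transient within the integrator's displacement guard on steep membranes
    daughter_offset_um: float = 7.5
    r0_um: float = 5.0
    exposure_cone_factor: float = 3.0    # cone height = factor * r0
    calcium_enabled: bool = False
    ca_tau_h: float = 1.0
    ca_band_um: float = 10.0             # granular band above diff height

    def __post_init__(self) -> None:
        for name in ("division_period_h", "spinous_dur_h", "granular_dur_h",
                     "flatten_tau_h", "desquam_dur_h", "diff_height_um", "r0_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"lifecycle.{name} must be > 0")
        if not 0 < self.target_aspect < 1:
            raise ValueError("lifecycle.target_aspect must be in (0, 1)")
        if self.daughter_offset_um > 2 * self.r0_um:
            raise ValueError("lifecycle.daughter_offset_um must be <= 2*r0")


def event_probability(dt: float, mean_h: float, rate_factor: float = 1.0) -> float:
    """Firing probability of an exponential clock of the given mean over dt."""
    return -math.expm1(-dt * rate_factor / mean_h)


def _hemisphere_direction(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - measure-zero redraw
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    v /= n
    v[2] = abs(v[2])
    return v


def attempt_division(cell: Cell, dt: float, rng, local_density: int,
                     params: LifecycleParams) -> Optional[Cell]:
    """One division attempt of an anchored stem over a timestep.

    Division fires with exponential-clock probability (mean
    ``division_period_h``), suppressed entirely when ``local_density`` — the
    number of neighbouring cell centres within one cell diameter — exceeds the
    crowding cap. The daughter starts as PROLIF at ``daughter_offset_um`` in a
    uniformly random upward-hemisphere direction; the stem stays put.
    """
    if cell.state != CellState.STEM:
        raise ValueError(f"attempt_division on non-STEM cell {cell.id}")
    if local_density > params.crowding_cap:
        return None
    rate_factor = 1.0
    if params.division_jitter > 0:
        rate_factor += params.division_jitter * (2.0 * rng.random() - 1.0)
    p = event_probability(dt, params.division_period_h, rate_factor)
    if rng.random() >= p:
        return None
    direction = _hemisphere_direction(rng)
    daughter = Cell(id=-1, pos=cell.pos + params.daughter_offset_um * direction,
                    r0=params.r0_um, a=params.r0_um, c=params.r0_um,
                    state=CellState.PROLIF)
    cell.age_in_state = 0.0
    return daughter


def update_state(cell: Cell, gap: float, dt: float, rng,
                 params: LifecycleParams, exposed: bool = True) -> Cell:
    """Advance the differentiation state machine of one cell by dt.

    ``gap`` is the cell's vertical clearance above the membrane; ``exposed``
    reports whether the surface-exposure cone above the cell is free (needed
    only for corneocyte desquamation; defaults to exposed).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    s = cell.state
    if s == CellState.STEM:
        cell.age_in_state += dt
        return cell
    if s == CellState.PROLIF:
        if gap > params.diff_height_um:
            cell.state = CellState.SPINOUS
            cell.age_in_state = 0.0
        else:
            cell.age_in_state += dt
        return cell
    if s == CellState.SPINOUS:
        factor = cell.ca if params.calcium_enabled else 1.0
        if factor > 0 and rng.random() < event_probability(
                dt, params.spinous_dur_h, factor):
            cell.state = CellState.GRANULAR
            cell.age_in_state = 0.0
        else:
            cell.age_in_state += dt
        return cell
    if s == CellState.GRANULAR:
        if rng.random() < event_probability(dt, params.granular_dur_h):
            cell.state = CellState.CORNEOCYTE
            cell.age_in_state = 0.0
        else:
            cell.age_in_state += dt
        return cell
    # CORNEOCYTE: desquamation only while exposed at the free surface
    if exposed and rng.random() < event_probability(dt, params.desquam_dur_h):
        cell.alive = False
    cell.age_in_state += dt
    return cell


def update_flattening(cell: Cell, dt: float, params: LifecycleParams) -> Cell:
    """Relax a corneocyte's aspect ratio q = c/a exponentially toward the
    terminal aspect, rescaling the semi-axes so a^2 c = r0^3 exactly."""
    if cell.state != CellState.CORNEOCYTE:
        raise ValueError("update_flattening applies to CORNEOCYTE cells only")
    if dt == 0:
        return cell
    q = cell.c / cell.a
    q = params.target_aspect + (q - params.target_aspect) * math.exp(
        -dt / params.flatten_tau_h)
    cell.a = cell.r0 * q ** (-1.0 / 3.0)
    cell.c = cell.r0 * q ** (2.0 / 3.0)
    return cell


def flatten_semi_axes(q: np.ndarray, r0: float) -> tuple:
    """Semi-axes (a, c) of an r0-volume ellipsoid with aspect ratio q = c/a."""
    a = r0 * q ** (-1.0 / 3.0)
    return a, r0 * q ** (2.0 / 3.0)


def update_calcium(cell: Cell, gap: float, dt: float,
                   params: LifecycleParams) -> Cell:
    """Relax the scalar calcium proxy toward its height-dependent target.

    The target rises linearly from 0 at the membrane to 1 at
    ``diff_height_um + ca_band_um`` of clearance; relaxation time constant
    ``ca_tau_h``. The value is clamped to [0, 1]. This proxy stands in for a
    full intracellular calcium reaction model and is disabled by default.
    """
    target = min(1.0, max(0.0, gap / (params.diff_height_um + params.ca_band_um)))
    cell.ca += (target - cell.ca) * (-math.expm1(-dt / params.ca_tau_h))
    cell.ca = min(1.0, max(0.0, cell.ca))
    return cell
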