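"""Basement-membrane geometry.

The simulated epidermis grows on a rigid basement membrane whose shape is one of

* ``flat`` — the zero surface, the control condition;
* ``sinusoidal`` — an isotropic product sinusoid ``h(x, y) =
  (A/2) sin(2*pi*x/lambda) sin(2*pi*y/lambda)`` whose peak-to-trough excursion is
  ``amplitude_um``; a 1D groove variant (``profile="grooves"``) is available for
  sensitivity studies;
* ``fiber_grid`` — the upper envelope of two orthogonal arrays of half-embedded
  cylinders (axis in the base plane, crown rising one fiber thickness above
  z = 0), an idealisation of a woven polyester textile characterised only by
  its fiber thickness and inter-fiber interval.

The lateral domain is periodic in x and y; all lengths are in micrometres and
z points from the membrane toward the air.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "MembraneSpec",
    "TexturePreset",
    "load_presets",
    "get_preset",
    "membrane_height",
    "membrane_gap",
    "place_stem_cells",
]

_KIND_CODES = {"flat": K.MKIND_FLAT, "sinusoidal": K.MKIND_SIN2D,
               "fiber_grid": K.MKIND_FIBER}


class ConfigurationError(ValueError):
    """Invalid membrane or run configuration."""


@dataclass(frozen=True)
class MembraneSpec:
    """Validated basement-membrane geometry with lateral domain extents."""

    kind: str = "flat"
    amplitude_um: float = 0.0
    wavelength_um: float = 100.0
    fiber_thickness_um: float = 60.0
    fiber_interval_um: float = 101.0
    domain_x_um: float = 100.0
    domain_y_um: float = 100.0
    profile: str = "bumps"  # sinusoidal only: "bumps" (2D product) or "grooves" (1D)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ConfigurationError(
                f"membrane.kind: unknown kind {self.kind!r}; "
                f"expected one of {sorted(_KIND_CODES)}")
        if self.domain_x_um <= 0 or self.domain_y_um <= 0:
            raise ConfigurationError("membrane.domain_*_um: domain extents must be > 0")
        if self.kind == "sinusoidal":
            if self.amplitude_um < 0:
                raise ConfigurationError("membrane.amplitude_um must be >= 0")
            if self.wavelength_um <= 0:
                raise ConfigurationError("membrane.wavelength_um must be > 0")
            if self.profile not in ("bumps", "grooves"):
                raise ConfigurationError(
                    "membrane.profile must be 'bumps' or 'grooves'")
            # the surface must close smoothly over the periodic seam: the
            # domain must hold a whole number of wavelengths (an odd number of
            # half-wavelengths leaves a mirror kink in the normal at the seam,
            # which traps cells in a force discontinuity)
            lam = self.wavelength_um
            for name, ext in (("domain_x_um", self.domain_x_um),
                              ("domain_y_um", self.domain_y_um)):
                m = max(1.0, np.rint(ext / lam))
                if abs(ext - m * lam) > 0.01 * ext:
                    raise ConfigurationError(
                        f"membrane.{name}={ext} is not a whole multiple of the "
                        f"wavelength ({lam} um) within 1%; the sinusoid would "
                        "not close smoothly across the periodic boundary")
        if self.kind == "fiber_grid":
            if self.fiber_thickness_um <= 0 or self.fiber_interval_um <= 0:
                raise ConfigurationError(
                    "membrane.fiber_*_um: fiber thickness and interval must be > 0")
            period = self.fiber_thickness_um + self.fiber_interval_um
            for name, ext in (("domain_x_um", self.domain_x_um),
                              ("domain_y_um", self.domain_y_um)):
                m = max(1.0, np.rint(ext / period))
                if abs(ext - m * period) > 0.01 * ext:
                    raise ConfigurationError(
                        f"membrane.{name}={ext} is not a multiple of the fiber "
                        f"period ({period} um) within 1%")

    @property
    def kind_code(self) -> int:
        if self.kind == "sinusoidal" and self.profile == "grooves":
            return K.MKIND_SIN1D
        return _KIND_CODES[self.kind]

    @property
    def fiber_period_um(self) -> float:
        return self.fiber_thickness_um + self.fiber_interval_um

    def kernel_args(self) -> tuple:
        """(kind, amp, lam, thick, period, dom_x, dom_y) for the numba kernels."""
        return (self.kind_code, self.amplitude_um, self.wavelength_um,
                self.fiber_thickness_um, self.fiber_period_um,
                self.domain_x_um, self.domain_y_um)

    @classmethod
    def from_preset(cls, name: str, domain_x_um: Optional[float] = None,
                    domain_y_um: Optional[float] = None,
                    target_extent_um: float = 100.0) -> "MembraneSpec":
        """Fiber-grid spec from a packaged textile preset.

        When the domain extents are not given they default to the whole-period
        multiple of the fiber period closest to ``target_extent_um``.
        """
        p = get_preset(name)
        period = p.fiber_thickness_um + p.fiber_interval_um
        if domain_x_um is None:
            domain_x_um = period * max(1, round(target_extent_um / period))
        if domain_y_um is None:
            domain_y_um = domain_x_um
        return cls(kind="fiber_grid", fiber_thickness_um=p.fiber_thickness_um,
                   fiber_interval_um=p.fiber_interval_um,
                   domain_x_um=domain_x_um, domain_y_um=domain_y_um)


@dataclass(frozen=True)
class TexturePreset:
    """A textile substrate (or the human papillary surface) characterised by
    fiber thickness (ridge height) and inter-fiber interval (undulation interval)."""

    name: str
    fiber_thickness_um: float
    fiber_interval_um: float


def load_presets() -> pd.DataFrame:
    """The packaged substrate table: ten polyester textiles plus the measured
    human papillary geometry (ridge height 51 um, interval 105 um)."""
    with importlib.resources.files("epidermsim").joinpath(
            "data/textile_presets.csv").open() as fh:
        return pd.read_csv(fh)


def get_preset(name: str) -> TexturePreset:
    table = load_presets()
    row = table[table["name"] == name]
    if row.empty:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(table['name'])}")
    r = row.iloc[0]
    return TexturePreset(r["name"], float(r["fiber_thickness_um"]),
                         float(r["fiber_interval_um"]))


def membrane_height(spec: MembraneSpec, x, y):
    """Surface height z(x, y) in um; accepts scalars or arrays, laterally periodic."""
    xs = np.asarray(x, dtype=np.float64)
    ys = np.asarray(y, dtype=np.float64)
    scalar = xs.ndim == 0 and ys.ndim == 0
    xs, ys = np.broadcast_arrays(np.atleast_1d(xs), np.atleast_1d(ys))
    out = np.empty(xs.shape, dtype=np.float64)
    flat_x = np.ascontiguousarray(xs, dtype=np.float64).ravel()
    flat_y = np.ascontiguousarray(ys, dtype=np.float64).ravel()
    flat_out = out.ravel()
    K.mem_height_arr(*spec.kernel_args(), flat_x, flat_y, flat_out)
    out = flat_out.reshape(xs.shape)
    return float(out.ravel()[0]) if scalar else out


def membrane_gap(spec: MembraneSpec, p):
    """Vertical clearance above the membrane and the outward unit surface normal.

    ``gap < 0`` means the point penetrates the surface. Total function: the
    lateral coordinates are wrapped into the periodic domain first.
    """
    p = np.asarray(p, dtype=np.float64)
    h = K.mem_height(*spec.kernel_args(), float(p[0]), float(p[1]))
    n = K.mem_normal(*spec.kernel_args(), float(p[0]), float(p[1]))
    return float(p[2]) - h, np.array(n)


def place_stem_cells(spec: MembraneSpec, spacing_um: float, rng,
                     jitter: float = 0.1) -> np.ndarray:
    """Seed stem cells on the membrane on a jittered hexagonal lattice.

    Returns an (n, 3) array of positions lying exactly on the surface. The
    lattice is stretched slightly so an integer number of columns and rows fit
    the periodic domain; jitter is uniform within ``+/- jitter * spacing_um``
    per lateral coordinate. Deterministic given (spec, spacing, rng state).
    """
    if spacing_um <= 0:
        raise ConfigurationError("spacing_um must be > 0")
    row_h = spacing_um * np.sqrt(3.0) / 2.0
    ncol = int(np.rint(spec.domain_x_um / spacing_um))
    nrow = int(np.rint(spec.domain_y_um / row_h))
    if ncol < 1 or nrow < 1:
        raise ConfigurationError(
            f"spacing_um={spacing_um} too large for domain "
            f"{spec.domain_x_um}x{spec.domain_y_um} um")
    sx = spec.domain_x_um / ncol
    sy = spec.domain_y_um / nrow
    xs = []
    ys = []
    for r in range(nrow):
        off = 0.5 * sx if (r % 2) else 0.0
        for c in range(ncol):
            xs.append(off + c * sx)
            ys.append((r + 0.5) * sy)
    xs = np.array(xs)
    ys = np.array(ys)
    if jitter > 0:
        xs = xs + rng.uniform(-jitter * spacing_um, jitter * spacing_um, xs.size)
        ys = ys + rng.uniform(-jitter * spacing_um, jitter * spacing_um, ys.size)
    xs %= spec.domain_x_um
    ys %= spec.domain_y_um
    zs = membrane_height(spec, xs, ys)
    return np.column_stack([xs, ys, zs])
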