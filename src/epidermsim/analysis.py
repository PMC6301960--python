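"""Tissue readouts from simulation snapshots.

Mirrors histological scoring of epidermal cross-sections: cells are partitioned
into the stratum corneum (corneocytes) and the living layer (everything else);
virtual sections are rasterised onto an (x, z) pixel grid with the membrane /
fiber profile masked out, and areas are reported per 100 um of section length.
Multi-condition replicate tables are compared with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cell_model import CellState
from .geometry import MembraneSpec, membrane_height
from .mechanics import SimState

__all__ = ["LayerMetrics", "count_layers", "section_areas",
           "thickness_profiles", "ThicknessProfile", "render_section",
           "save_section_image", "compare_conditions", "CompareResult",
           "layer_metrics", "MEMBRANE_RGB", "LIVING_RGB", "SC_RGB"]

# Section color code: membrane green, living keratinocytes purple, cornified red
MEMBRANE_RGB = (34, 139, 34)
LIVING_RGB = (128, 0, 128)
SC_RGB = (220, 20, 60)
_BG_RGB = (255, 255, 255)


@dataclass(frozen=True)
class LayerMetrics:
    n_corneocytes: int
    n_living: int
    sc_area_per100um: float
    living_area_per100um: float
    mean_sc_thickness_um: float
    mean_living_thickness_um: float
    interface_roughness_um: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def count_layers(snapshot: SimState) -> Tuple[int, int]:
    """(corneocyte count, living count): the SC/living partition of the snapshot."""
    n_sc = int(np.sum(snapshot.state == int(CellState.CORNEOCYTE)))
    return n_sc, snapshot.n_cells - n_sc


def _rasterize(snapshot: SimState, spec: MembraneSpec, y0: float,
               slab_um: float, pixel_um: float):
    """Boolean SC / living / membrane rasters of the slab y in [y0, y0+slab].

    Every cell whose ellipsoid intersects the slab is drawn as its full (x, z)
    ellipse cross-section (a histology-like projection); corneocytes overwrite
    living pixels on ties; pixels at or below the membrane profile (sampled at
    the slab mid-plane) are masked out.
    """
    if slab_um <= 0:
        raise ValueError("slab_um must be > 0")
    if not (0.0 <= y0 and y0 + slab_um <= spec.domain_y_um):
        raise ValueError(
            f"slab [{y0}, {y0 + slab_um}] outside domain_y "
            f"[0, {spec.domain_y_um}]")
    y_mid = y0 + 0.5 * slab_um
    dom_x = spec.domain_x_um
    nx = max(1, int(round(dom_x / pixel_um)))
    xs = (np.arange(nx) + 0.5) * pixel_um
    h_profile = membrane_height(spec, xs, np.full(nx, y_mid))

    z_lo = min(0.0, float(np.min(snapshot.pos[:, 2] - snapshot.cc))
               if snapshot.n_cells else 0.0)
    z_hi = max(float(np.max(h_profile)) + pixel_um,
               float(np.max(snapshot.pos[:, 2] + snapshot.cc)) + pixel_um
               if snapshot.n_cells else pixel_um)
    nz = max(1, int(np.ceil((z_hi - z_lo) / pixel_um)))
    zs = z_lo + (np.arange(nz) + 0.5) * pixel_um

    sc = np.zeros((nz, nx), dtype=bool)
    living = np.zeros((nz, nx), dtype=bool)
    corneo_code = int(CellState.CORNEOCYTE)
    dy = np.abs(snapshot.pos[:, 1] - y_mid) if snapshot.n_cells else np.empty(0)
    if dy.size:
        dy = np.minimum(dy, spec.domain_y_um - dy)  # periodic in y
    for i in range(snapshot.n_cells):
        a = snapshot.aa[i]
        if dy[i] > a + 0.5 * slab_um:
            continue
        cz = snapshot.pos[i, 2]
        c = snapshot.cc[i]
        iz0 = max(0, int((cz - c - z_lo) / pixel_um))
        iz1 = min(nz, int(np.ceil((cz + c - z_lo) / pixel_um)) + 1)
        if iz1 <= iz0:
            continue
        target = sc if snapshot.state[i] == corneo_code else living
        cx = snapshot.pos[i, 0]
        # draw at the cell's x and, near the seam, at its periodic images
        for xoff in (-dom_x, 0.0, dom_x):
            x0 = cx + xoff
            if x0 + a < 0 or x0 - a > dom_x:
                continue
            ix0 = max(0, int((x0 - a) / pixel_um))
            ix1 = min(nx, int(np.ceil((x0 + a) / pixel_um)) + 1)
            if ix1 <= ix0:
                continue
            u = (xs[ix0:ix1] - x0) / a
            v = (zs[iz0:iz1, None] - cz) / c
            target[iz0:iz1, ix0:ix1] |= (u[None, :] ** 2 + v ** 2) <= 1.0
    membrane = zs[:, None] <= h_profile[None, :]
    sc &= ~membrane
    living &= ~membrane & ~sc  # corneocyte wins ties
    return sc, living, membrane, xs, zs


def section_areas(snapshot: SimState, spec: MembraneSpec, y0: float = 0.0,
                  slab_um: float = 10.0,
                  pixel_um: float = 0.25) -> Tuple[float, float]:
    """(SC area, living area) in um^2 per 100 um of section length.

    Pixels below the membrane/fiber profile are excluded, mirroring the removal
    of fiber cross-sections from stained-section images before quantification.
    """
    sc, living, _, _, _ = _rasterize(snapshot, spec, y0, slab_um, pixel_um)
    px2 = pixel_um * pixel_um
    norm = 100.0 / spec.domain_x_um
    return float(sc.sum() * px2 * norm), float(living.sum() * px2 * norm)


@dataclass(frozen=True)
class ThicknessProfile:
    mean_living_um: float
    mean_sc_um: float
    interface_roughness_um: float
    living_um: np.ndarray = field(repr=False, default=None)
    sc_um: np.ndarray = field(repr=False, default=None)
    interface_um: np.ndarray = field(repr=False, default=None)


def thickness_profiles(snapshot: SimState, spec: MembraneSpec,
                       bins: Optional[int] = None) -> ThicknessProfile:
    """Per lateral-bin living and SC thickness and the interface roughness.

    In each (x, y) bin: living thickness = highest living-cell top minus the
    membrane height at the bin centre; SC thickness = highest corneocyte top
    minus the highest living top, floored at zero. Roughness is the standard
    deviation over bins of the SC/living interface height. Empty bins
    contribute zero thickness, so bins must not be much smaller than a cell:
    the default is one bin per ~10 um (a cell diameter) of lateral extent.
    """
    if bins is None:
        bins = max(4, int(round(min(spec.domain_x_um, spec.domain_y_um)
                                / 10.0)))
    if bins < 4:
        raise ValueError("bins must be >= 4")
    bx = spec.domain_x_um / bins
    by = spec.domain_y_um / bins
    ix = np.clip((snapshot.pos[:, 0] // bx).astype(int), 0, bins - 1)
    iy = np.clip((snapshot.pos[:, 1] // by).astype(int), 0, bins - 1)
    tops = snapshot.pos[:, 2] + snapshot.cc
    corneo = snapshot.state == int(CellState.CORNEOCYTE)

    cx = (np.arange(bins) + 0.5) * bx
    cy = (np.arange(bins) + 0.5) * by
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    h = membrane_height(spec, gx.ravel(), gy.ravel()).reshape(bins, bins)

    living_top = np.full((bins, bins), -np.inf)
    sc_top = np.full((bins, bins), -np.inf)
    for i in range(snapshot.n_cells):
        tgt = sc_top if corneo[i] else living_top
        if tops[i] > tgt[ix[i], iy[i]]:
            tgt[ix[i], iy[i]] = tops[i]

    has_living = np.isfinite(living_top)
    has_sc = np.isfinite(sc_top)
    living_thick = np.where(has_living, np.maximum(living_top - h, 0.0), 0.0)
    interface = np.where(has_living, np.maximum(living_top, h), h)
    sc_thick = np.where(has_sc, np.maximum(sc_top - interface, 0.0), 0.0)
    return ThicknessProfile(
        mean_living_um=float(living_thick.mean()),
        mean_sc_um=float(sc_thick.mean()),
        interface_roughness_um=float(np.std(interface)),
        living_um=living_thick, sc_um=sc_thick, interface_um=interface)


def layer_metrics(snapshot: SimState, spec: MembraneSpec, y0: float = 0.0,
                  slab_um: float = 10.0, pixel_um: float = 0.25,
                  bins: Optional[int] = None) -> LayerMetrics:
    """All per-snapshot readouts bundled into one record."""
    n_sc, n_living = count_layers(snapshot)
    sc_area, living_area = section_areas(snapshot, spec, y0, slab_um, pixel_um)
    prof = thickness_profiles(snapshot, spec, bins)
    return LayerMetrics(n_sc, n_living, sc_area, living_area,
                        prof.mean_sc_um, prof.mean_living_um,
                        prof.interface_roughness_um)


def render_section(snapshot: SimState, spec: MembraneSpec, y0: float = 0.0,
                   slab_um: float = 10.0, pixel_um: float = 0.5) -> np.ndarray:
    """RGB (H, W, 3) uint8 cross-section image: membrane green, living
    keratinocytes purple, cornified cells red; row 0 is the topmost z."""
    sc, living, membrane, xs, zs = _rasterize(snapshot, spec, y0, slab_um,
                                              pixel_um)
    img = np.empty(sc.shape + (3,), dtype=np.uint8)
    img[...] = _BG_RGB
    img[living] = LIVING_RGB
    img[sc] = SC_RGB
    img[membrane] = MEMBRANE_RGB
    return img[::-1]


def save_section_image(img: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, img)


@dataclass(frozen=True)
class CompareResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    group_means: pd.Series

    def significant_vs(self, reference: str) -> pd.Series:
        """Tukey rejection flags of every group against a reference condition."""
        t = self.tukey
        mask = (t["group1"] == reference) | (t["group2"] == reference)
        rows = t[mask]
        other = np.where(rows["group1"] == reference, rows["group2"],
                         rows["group1"])
        return pd.Series(rows["reject"].to_numpy(), index=other)


def compare_conditions(groups: Mapping[str, Sequence[float]],
                       alpha: float = 0.05) -> CompareResult:
    """One-way ANOVA F/p plus Tukey HSD pairwise flags over replicate metrics."""
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 replicates")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    f, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(f):  # all groups identical constants
        f, p = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:],
                         columns=[str(c) for c in res.summary().data[0]])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    means = pd.Series({k: float(v.mean()) for k, v in arrays.items()})
    return CompareResult(float(f), float(p), tukey, means)
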