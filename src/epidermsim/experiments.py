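"""Seeded in-silico experiments.

Each driver runs paired, seeded simulations across membrane conditions and
reduces them to tidy replicate tables: flat vs sinusoidal membrane,
amplitude/wavelength sweeps, and the textile substrate panel. Paired-seed
design: every condition reuses the same per-replicate seed so condition
contrasts are not diluted by Monte-Carlo variance. A fixture generator builds
small hand-specified cell configurations for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .analysis import compare_conditions, count_layers, layer_metrics, \
    section_areas, thickness_profiles, CompareResult
from .cell_model import CellState, LifecycleParams, flatten_semi_axes
from .geometry import MembraneSpec, membrane_height, get_preset
from .mechanics import ForceParams, RunParams, SimConfig, SimState, run

__all__ = ["ExperimentPlan", "ConditionRun", "run_plan",
           "experiment_flat_vs_sinusoidal", "experiment_amplitude_wavelength_sweep",
           "experiment_textile_panel", "make_fixture", "replicate_seeds",
           "sinusoid_domain_extent"]

#: Desk-scale lateral extent (um). The headline comparison uses a 100x100 um
#: domain, 1/9 the area of the 300x300 um reference region of interest; the
#: full region is available via ``full_roi=True``.
DESK_EXTENT_UM = 100.0
FULL_ROI_EXTENT_UM = 300.0


def replicate_seeds(base_seed: int, replicates: int) -> List[int]:
    """Independent per-replicate seeds (< 2^31), shared across conditions."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(replicates, np.uint64)]


@dataclass(frozen=True)
class ExperimentPlan:
    name: str
    conditions: Dict[str, MembraneSpec]
    replicates: int
    seeds: List[int]             # length = replicates * len(conditions)
    sim_overrides: dict = field(default_factory=dict)
    metrics: Tuple[str, ...] = ("n_corneocytes", "n_living",
                                "mean_living_thickness_um",
                                "mean_sc_thickness_um")

    def __post_init__(self) -> None:
        if len(self.seeds) != self.replicates * len(self.conditions):
            raise ValueError("len(seeds) must equal replicates * len(conditions)")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition names must be unique")


@dataclass
class ConditionRun:
    condition: str
    replicate: int
    seed: int
    series: pd.DataFrame          # one row per snapshot
    final: dict                   # metric name -> value at the last snapshot
    spec: MembraneSpec


def _series_frame(snapshots) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        c = s.counts_by_state()
        rows.append({"t_h": s.t, "n_cells": s.n_cells, "births": s.births,
                     "removals": s.removals, "n_stem": c["STEM"],
                     "n_corneocytes": c["CORNEOCYTE"],
                     "n_living": s.n_cells - c["CORNEOCYTE"]})
    return pd.DataFrame(rows)


def _base_config(spec: MembraneSpec, seed: int, overrides: dict) -> SimConfig:
    ov = dict(overrides or {})
    lp = LifecycleParams(**ov.pop("lifecycle", {}))
    fp = ForceParams(**ov.pop("forces", {}))
    run_kwargs = ov.pop("run", {})
    if ov:
        raise ValueError(f"unknown sim_overrides {sorted(ov)}")
    rp = RunParams(seed=seed, **run_kwargs)
    return SimConfig(membrane=spec, lifecycle=lp, forces=fp, run=rp)


def run_condition(spec: MembraneSpec, seed: int, condition: str = "",
                  replicate: int = 0, sim_overrides: Optional[dict] = None,
                  keep_snapshots: bool = False) -> ConditionRun:
    config = _base_config(spec, seed, sim_overrides or {})
    snapshots = run(config)
    last = snapshots[-1]
    n_sc, n_living = count_layers(last)
    prof = thickness_profiles(last, spec)
    # histology-style section quantification at the domain mid-plane
    slab = min(10.0, spec.domain_y_um)
    sc_area, living_area = section_areas(
        last, spec, y0=0.5 * (spec.domain_y_um - slab), slab_um=slab,
        pixel_um=0.25)
    final = {"n_corneocytes": n_sc, "n_living": n_living,
             "mean_living_thickness_um": prof.mean_living_um,
             "mean_sc_thickness_um": prof.mean_sc_um,
             "sc_area_per100um": sc_area,
             "living_area_per100um": living_area,
             "interface_roughness_um": prof.interface_roughness_um}
    cr = ConditionRun(condition, replicate, seed, _series_frame(snapshots),
                      final, spec)
    if keep_snapshots:
        cr.snapshots = snapshots
    return cr


def run_plan(plan: ExperimentPlan,
             keep_snapshots: bool = False) -> List[ConditionRun]:
    """Execute every (condition, replicate) cell of the plan, reproducibly."""
    runs = []
    i = 0
    for name, spec in plan.conditions.items():
        for rep in range(plan.replicates):
            runs.append(run_condition(spec, plan.seeds[i], name, rep,
                                      plan.sim_overrides, keep_snapshots))
            i += 1
    return runs


def _table(runs: List[ConditionRun]) -> pd.DataFrame:
    return pd.DataFrame([{"condition": r.condition, "replicate": r.replicate,
                          "seed": r.seed, **r.final} for r in runs])


# ---------------------------------------------------------------------------
# Flat vs sinusoidal membrane
# ---------------------------------------------------------------------------

@dataclass
class FlatVsSinReport:
    table: pd.DataFrame
    summary: pd.DataFrame
    paired_sc_wins: int        # replicates where sinusoidal SC count > flat
    paired_living_wins: int
    replicates: int
    domain_um: float
    scale_factor: float        # (domain / 300)^2, the area scaling vs full ROI
    runs: List[ConditionRun]


def experiment_flat_vs_sinusoidal(replicates: int = 5, base_seed: int = 0,
                                  amplitude_um: float = 50.0,
                                  wavelength_um: float = 100.0,
                                  full_roi: bool = False,
                                  sim_overrides: Optional[dict] = None,
                                  sinusoidal_spec: Optional[MembraneSpec] = None,
                                  keep_snapshots: bool = False) -> FlatVsSinReport:
    """Paired flat-vs-sinusoidal comparison of SC and living-layer cell counts.

    Defaults: sinusoid amplitude 50 um / wavelength 100 um (the measured human
    papillary geometry, rounded) on a desk-scale 100x100 um domain; pass
    ``full_roi=True`` for the 300x300 um region of interest.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ext = FULL_ROI_EXTENT_UM if full_roi else DESK_EXTENT_UM
    flat = MembraneSpec(kind="flat", domain_x_um=ext, domain_y_um=ext)
    sin = sinusoidal_spec if sinusoidal_spec is not None else MembraneSpec(
        kind="sinusoidal", amplitude_um=amplitude_um,
        wavelength_um=wavelength_um, domain_x_um=ext, domain_y_um=ext)
    seeds = replicate_seeds(base_seed, replicates)
    plan = ExperimentPlan("flat_vs_sinusoidal",
                          {"flat": flat, "sinusoidal": sin}, replicates,
                          seeds + seeds, sim_overrides or {})
    runs = run_plan(plan, keep_snapshots)
    table = _table(runs)
    piv_sc = table.pivot(index="replicate", columns="condition",
                         values="n_corneocytes")
    piv_lv = table.pivot(index="replicate", columns="condition",
                         values="n_living")
    summary = table.groupby("condition")[
        ["n_corneocytes", "n_living", "mean_living_thickness_um",
         "mean_sc_thickness_um"]].agg(["mean", "std"])
    return FlatVsSinReport(
        table=table, summary=summary,
        paired_sc_wins=int((piv_sc["sinusoidal"] > piv_sc["flat"]).sum()),
        paired_living_wins=int((piv_lv["sinusoidal"] > piv_lv["flat"]).sum()),
        replicates=replicates, domain_um=ext,
        scale_factor=(ext / FULL_ROI_EXTENT_UM) ** 2, runs=runs)


# ---------------------------------------------------------------------------
# Amplitude / wavelength sweep
# ---------------------------------------------------------------------------

def sinusoid_domain_extent(wavelength_um: float,
                           target_um: float = DESK_EXTENT_UM) -> float:
    """Whole-multiple of the wavelength closest to the target extent, so the
    sinusoid closes smoothly over the periodic boundary."""
    return wavelength_um * max(1, round(target_um / wavelength_um))


@dataclass
class SweepReport:
    table: pd.DataFrame            # one row per (amplitude, wavelength)
    replicate_table: pd.DataFrame  # one row per run
    spearman_amplitude: float      # rank corr. of excess living thickness with A
    spearman_wavelength: float     # ... and with wavelength
    runs: List[ConditionRun]
    controls: pd.DataFrame = None  # per-domain flat-control thickness
    spearman_sc_amplitude: float = float("nan")   # same, for excess SC thickness
    spearman_sc_wavelength: float = float("nan")


def experiment_amplitude_wavelength_sweep(
        amplitudes: Sequence[float] = (10.0, 30.0, 50.0),
        wavelengths: Sequence[float] = (60.0, 100.0, 200.0),
        replicates: int = 2, base_seed: int = 0,
        sim_overrides: Optional[dict] = None) -> SweepReport:
    """Grid of sinusoidal membranes; reports living thickness per
    (amplitude, wavelength) and the rank correlation of the undulation effect
    with amplitude and with wavelength.

    Each condition's domain is the whole multiple of its wavelength closest to
    the desk-scale extent, so different wavelength columns run on different
    domain extents. Tissue output per unit area carries a finite-size effect
    of the periodic domain, so the undulation effect is scored as *excess*
    living thickness over a flat control run on the same domain with the same
    seed; the rank correlations are computed on that excess.
    """
    conditions = {}
    meta = {}
    extents = set()
    for a in amplitudes:
        for lam in wavelengths:
            ext = sinusoid_domain_extent(lam)
            extents.add(ext)
            name = f"A{a:g}_L{lam:g}"
            conditions[name] = MembraneSpec(
                kind="sinusoidal", amplitude_um=a, wavelength_um=lam,
                domain_x_um=ext, domain_y_um=ext)
            meta[name] = (a, lam, ext)
    for ext in sorted(extents):
        name = f"flat_{ext:g}"
        conditions[name] = MembraneSpec(kind="flat", domain_x_um=ext,
                                        domain_y_um=ext)
        meta[name] = (0.0, np.nan, ext)
    seeds = replicate_seeds(base_seed, replicates)
    plan = ExperimentPlan("amplitude_wavelength_sweep", conditions, replicates,
                          seeds * len(conditions), sim_overrides or {})
    runs = run_plan(plan)
    rep_table = _table(runs)
    rep_table["amplitude_um"] = [meta[c][0] for c in rep_table["condition"]]
    rep_table["wavelength_um"] = [meta[c][1] for c in rep_table["condition"]]
    rep_table["domain_um"] = [meta[c][2] for c in rep_table["condition"]]

    is_control = rep_table["condition"].str.startswith("flat_")
    controls = rep_table[is_control].groupby("domain_um")[
        "mean_living_thickness_um"].mean()
    sc_controls = rep_table[is_control].groupby("domain_um")[
        "mean_sc_thickness_um"].mean()
    sweep_rows = rep_table[~is_control].copy()
    sweep_rows["excess_living_thickness_um"] = (
        sweep_rows["mean_living_thickness_um"]
        - sweep_rows["domain_um"].map(controls))
    sweep_rows["excess_sc_thickness_um"] = (
        sweep_rows["mean_sc_thickness_um"]
        - sweep_rows["domain_um"].map(sc_controls))
    g = sweep_rows.groupby(["amplitude_um", "wavelength_um"])
    table = g.agg(
        mean_living_thickness_um=("mean_living_thickness_um", "mean"),
        excess_living_thickness_um=("excess_living_thickness_um", "mean"),
        sd_living_thickness_um=("mean_living_thickness_um", "std"),
        mean_sc_thickness_um=("mean_sc_thickness_um", "mean"),
        excess_sc_thickness_um=("excess_sc_thickness_um", "mean"),
        mean_n_corneocytes=("n_corneocytes", "mean"),
        sd_n_corneocytes=("n_corneocytes", "std"),
    ).reset_index()
    rho_a = sps.spearmanr(table["amplitude_um"],
                          table["excess_living_thickness_um"]).statistic
    rho_l = sps.spearmanr(table["wavelength_um"],
                          table["excess_living_thickness_um"]).statistic
    rho_sc_a = sps.spearmanr(table["amplitude_um"],
                             table["excess_sc_thickness_um"]).statistic
    rho_sc_l = sps.spearmanr(table["wavelength_um"],
                             table["excess_sc_thickness_um"]).statistic
    return SweepReport(table, sweep_rows, float(rho_a), float(rho_l), runs,
                       controls.reset_index(), float(rho_sc_a),
                       float(rho_sc_l))


# ---------------------------------------------------------------------------
# Textile panel
# ---------------------------------------------------------------------------

@dataclass
class TextileReport:
    table: pd.DataFrame
    summary: pd.DataFrame
    ranking: List[str]              # condition names, thickest SC first
    comparison: Optional[CompareResult]
    metric: str
    runs: List[ConditionRun]


def experiment_textile_panel(presets: Sequence[str] = ("#200", "#255", "#300"),
                             replicates: int = 3, base_seed: int = 0,
                             metric: str = "mean_sc_thickness_um",
                             sim_overrides: Optional[dict] = None) -> TextileReport:
    """Fiber-grid simulations for packaged textile presets plus a flat control.

    Reports per-condition means/SDs, a thickness ranking and — with enough
    replicates — Tukey HSD flags against the control. The ranking is reported
    as-is; no particular textile is asserted to come first.
    """
    conditions = {"control": MembraneSpec(kind="flat",
                                          domain_x_um=DESK_EXTENT_UM,
                                          domain_y_um=DESK_EXTENT_UM)}
    for name in presets:
        get_preset(name)  # raises with the available names listed
        conditions[name] = MembraneSpec.from_preset(
            name, target_extent_um=DESK_EXTENT_UM)
    seeds = replicate_seeds(base_seed, replicates)
    plan = ExperimentPlan("textile_panel", conditions, replicates,
                          seeds * len(conditions), sim_overrides or {})
    runs = run_plan(plan)
    table = _table(runs)
    summary = table.groupby("condition")[
        ["n_corneocytes", "n_living", "mean_sc_thickness_um",
         "mean_living_thickness_um"]].agg(["mean", "std"])
    means = table.groupby("condition")[metric].mean()
    ranking = list(means.sort_values(ascending=False).index)
    comparison = None
    if replicates >= 2:
        groups = {c: table.loc[table["condition"] == c, metric].to_numpy()
                  for c in conditions}
        comparison = compare_conditions(groups)
    return TextileReport(table, summary, ranking, comparison, metric, runs)


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: Optional[dict] = None,
                 seed: int = 0) -> SimState:
    """Deterministic hand-specified snapshots for unit tests.

    Kinds: ``two_layer_slab`` (living slab of known thickness under an SC slab),
    ``single_stem`` (one anchored stem on a flat membrane), ``random_cloud``
    (N cells of random states/positions for force-oracle tests).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "two_layer_slab":
        living = p.pop("living_um", 50.0)
        sc = p.pop("sc_um", 20.0)
        domain = p.pop("domain_um", 100.0)
        nx = p.pop("nx", 16)
        ny = p.pop("ny", nx)
        r0 = p.pop("r0_um", 5.0)
        aspect = p.pop("aspect", 0.2)
        _reject_extra(p, kind)
        a_sc, c_sc = flatten_semi_axes(np.float64(aspect), r0)
        xs = (np.arange(nx) + 0.5) * (domain / nx)
        ys = (np.arange(ny) + 0.5) * (domain / ny)
        gx, gy = [g.ravel() for g in np.meshgrid(xs, ys, indexing="ij")]
        n = gx.size
        pos = np.concatenate([
            np.column_stack([gx, gy, np.full(n, living - r0)]),
            np.column_stack([gx, gy, np.full(n, living + sc - c_sc)])])
        aa = np.concatenate([np.full(n, r0), np.full(n, float(a_sc))])
        cc = np.concatenate([np.full(n, r0), np.full(n, float(c_sc))])
        states = np.concatenate([
            np.full(n, int(CellState.SPINOUS), np.uint8),
            np.full(n, int(CellState.CORNEOCYTE), np.uint8)])
    elif kind == "single_stem":
        domain = p.pop("domain_um", 100.0)
        r0 = p.pop("r0_um", 5.0)
        _reject_extra(p, kind)
        pos = np.array([[domain / 2, domain / 2, 0.0]])
        aa = cc = np.array([r0])
        states = np.array([int(CellState.STEM)], np.uint8)
    elif kind == "random_cloud":
        n = p.pop("n", 200)
        domain = p.pop("domain_um", 100.0)
        zmax = p.pop("zmax_um", 60.0)
        r0 = p.pop("r0_um", 5.0)
        _reject_extra(p, kind)
        pos = np.column_stack([rng.uniform(0, domain, n),
                               rng.uniform(0, domain, n),
                               rng.uniform(0, zmax, n)])
        states = rng.integers(0, 5, n).astype(np.uint8)
        q = rng.uniform(0.2, 1.0, n)
        a_fl, c_fl = flatten_semi_axes(q, r0)
        corneo = states == int(CellState.CORNEOCYTE)
        aa = np.where(corneo, a_fl, r0)
        cc = np.where(corneo, c_fl, r0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    n = pos.shape[0]
    return SimState(pos, aa, cc, states, np.zeros(n), np.zeros(n),
                    pos[:, :2].copy(), np.arange(n, dtype=np.int64),
                    rng=np.random.default_rng(seed))


def _reject_extra(p: dict, kind: str) -> None:
    if p:
        raise ValueError(f"unknown params for fixture {kind!r}: {sorted(p)}")
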