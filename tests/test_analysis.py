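"""Tissue readouts: layer partition, section rasterisation, thickness profiles,
rendering and multi-condition statistics."""

import numpy as np
import pandas as pd
import pytest

from epidermsim.analysis import (LIVING_RGB, MEMBRANE_RGB, SC_RGB,
                                 compare_conditions, count_layers,
                                 layer_metrics, render_section, section_areas,
                                 thickness_profiles)
from epidermsim.cell_model import CellState, flatten_semi_axes
from epidermsim.experiments import make_fixture
from epidermsim.geometry import MembraneSpec
from epidermsim.mechanics import SimState


def state_of(positions, states, aa=None, cc=None):
    pos = np.asarray(positions, float).reshape(-1, 3)
    n = pos.shape[0]
    aa = np.full(n, 5.0) if aa is None else np.asarray(aa, float)
    cc = np.full(n, 5.0) if cc is None else np.asarray(cc, float)
    return SimState(pos, aa, cc, np.asarray(states, np.uint8), np.zeros(n),
                    np.zeros(n), pos[:, :2].copy(),
                    np.arange(n, dtype=np.int64))


class TestCountLayers:
    def test_partition_of_mixed_fixture(self):
        states = [int(CellState.CORNEOCYTE)] * 3 + [
            int(CellState.STEM), int(CellState.PROLIF), int(CellState.SPINOUS),
            int(CellState.GRANULAR), int(CellState.SPINOUS)]
        s = state_of(np.zeros((8, 3)), states)
        assert count_layers(s) == (3, 5)

    def test_empty_snapshot(self):
        s = state_of(np.zeros((0, 3)), [])
        assert count_layers(s) == (0, 0)

    def test_counts_sum_to_total_for_random_fixtures(self, rng):
        for seed in range(100):
            s = make_fixture("random_cloud", {"n": int(rng.integers(1, 60))},
                             seed=seed)
            n_sc, n_living = count_layers(s)
            assert n_sc + n_living == s.n_cells


class TestSectionAreas:
    def test_single_corneocyte_ellipse_area(self, flat_spec):
        # ellipse semi-axes (10, 2): area pi*10*2, domain_x = 100 -> per-100um
        # normalisation is exactly 1
        s = state_of([[50.0, 5.0, 40.0]], [int(CellState.CORNEOCYTE)],
                     aa=[10.0], cc=[2.0])
        sc, living = section_areas(s, flat_spec, y0=0.0, slab_um=10.0,
                                   pixel_um=0.25)
        assert living == 0.0
        assert sc == pytest.approx(np.pi * 10 * 2, rel=0.02)

    def test_cell_below_membrane_fully_masked(self):
        spec = MembraneSpec(kind="sinusoidal", amplitude_um=50,
                            wavelength_um=100)
        # the sinusoid peaks at 25 um over (25, 25); a cell topping out at
        # z = 15 there sits entirely below the surface
        s = state_of([[25.0, 25.0, 10.0]], [int(CellState.SPINOUS)])
        sc, living = section_areas(s, spec, y0=20.0, slab_um=10.0)
        assert sc == 0.0 and living == 0.0

    def test_rasterisation_converges_to_fine_grid(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        fine = section_areas(s, flat_spec, y0=45.0, slab_um=10.0,
                             pixel_um=0.05)
        mid = section_areas(s, flat_spec, y0=45.0, slab_um=10.0, pixel_um=0.1)
        default = section_areas(s, flat_spec, y0=45.0, slab_um=10.0,
                                pixel_um=0.25)
        for m, f in zip(mid, fine):
            assert m == pytest.approx(f, rel=0.01)
        for d, f in zip(default, fine):
            assert d == pytest.approx(f, rel=0.02)

    def test_translation_by_one_period_invariant(self):
        spec = MembraneSpec(kind="sinusoidal", amplitude_um=20,
                            wavelength_um=50)
        s = make_fixture("two_layer_slab", seed=0)
        a0 = section_areas(s, spec, y0=45.0, slab_um=10.0)
        shifted = state_of(s.pos + np.array([50.0, 0.0, 0.0]), s.state,
                           s.aa, s.cc)
        shifted.pos[:, 0] %= spec.domain_x_um
        a1 = section_areas(shifted, spec, y0=45.0, slab_um=10.0)
        for u, v in zip(a0, a1):
            assert u == pytest.approx(v, rel=0.01)

    def test_slab_outside_domain_raises(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        with pytest.raises(ValueError, match="outside"):
            section_areas(s, flat_spec, y0=95.0, slab_um=10.0)


class TestThicknessProfiles:
    def test_no_corneocytes_means_zero_sc(self, flat_spec):
        s = state_of([[50, 50, 30.0]], [int(CellState.SPINOUS)])
        prof = thickness_profiles(s, flat_spec, bins=4)
        assert np.all(prof.sc_um == 0.0)

    def test_two_layer_slab_exact_thicknesses(self, flat_spec):
        s = make_fixture("two_layer_slab",
                         {"living_um": 50.0, "sc_um": 20.0, "nx": 16}, seed=0)
        prof = thickness_profiles(s, flat_spec, bins=16)
        assert prof.mean_living_um == pytest.approx(50.0)
        assert prof.mean_sc_um == pytest.approx(20.0)
        assert prof.interface_roughness_um == pytest.approx(0.0)

    def test_alternating_interface_offsets_give_their_std(self, flat_spec):
        # interface at 50 +/- 5 um in alternating x-bins -> roughness exactly 5
        tops = []
        states = []
        for i in range(16):
            x = (i + 0.5) * 6.25
            z_top = 50.0 + (5.0 if i % 2 else -5.0)
            for j in range(16):
                y = (j + 0.5) * 6.25
                tops.append([x, y, z_top - 5.0])
                states.append(int(CellState.SPINOUS))
        s = state_of(tops, states)
        prof = thickness_profiles(s, flat_spec, bins=16)
        assert prof.interface_roughness_um == pytest.approx(5.0)

    def test_bins_validated(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        with pytest.raises(ValueError):
            thickness_profiles(s, flat_spec, bins=2)


class TestRenderSection:
    def test_empty_snapshot_shows_only_membrane(self):
        spec = MembraneSpec(kind="sinusoidal", amplitude_um=20,
                            wavelength_um=50)
        s = state_of(np.zeros((0, 3)), [])
        img = render_section(s, spec, y0=10.0, slab_um=10.0, pixel_um=0.5)
        colors = {tuple(c) for c in img.reshape(-1, 3)}
        assert MEMBRANE_RGB in colors
        assert LIVING_RGB not in colors and SC_RGB not in colors

    def test_color_code_and_dimensions(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        px = 0.5
        img = render_section(s, flat_spec, y0=45.0, slab_um=10.0, pixel_um=px)
        assert img.shape[1] == round(flat_spec.domain_x_um / px)
        colors = {tuple(c) for c in img.reshape(-1, 3)}
        assert LIVING_RGB in colors and SC_RGB in colors

    def test_sc_drawn_above_living(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        img = render_section(s, flat_spec, y0=45.0, slab_um=10.0, pixel_um=0.5)
        rows_sc = np.where(np.all(img == SC_RGB, axis=-1).any(axis=1))[0]
        rows_lv = np.where(np.all(img == LIVING_RGB, axis=-1).any(axis=1))[0]
        assert rows_sc.mean() < rows_lv.mean()  # row 0 is the top


class TestCompareConditions:
    def test_anova_oracle_two_groups(self):
        # groups {1,2,3} vs {4,5,6}: between-group MS 13.5, within-group MS 1
        res = compare_conditions({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.f_statistic == pytest.approx(13.5)
        assert 0 < res.p_value < 0.05

    def test_identical_groups_give_zero_f(self):
        res = compare_conditions({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)

    def test_tukey_flags_symmetric(self):
        res = compare_conditions({"a": [1, 2, 3], "b": [4, 5, 6],
                                  "c": [1.5, 2.5, 3.5]})
        t = res.tukey
        for _, row in t.iterrows():
            mirror = t[(t["group1"] == row["group2"]) &
                       (t["group2"] == row["group1"])]
            if not mirror.empty:
                assert mirror.iloc[0]["reject"] == row["reject"]
        flags = res.significant_vs("a")
        assert set(flags.index) == {"b", "c"}

    def test_too_few_replicates_names_condition(self):
        with pytest.raises(ValueError, match="solo"):
            compare_conditions({"a": [1, 2, 3], "solo": [4]})

    def test_too_few_conditions(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": [1, 2, 3]})


class TestLayerMetricsBundle:
    def test_fields_consistent_with_parts(self, flat_spec):
        s = make_fixture("two_layer_slab", seed=0)
        m = layer_metrics(s, flat_spec, y0=45.0, bins=16)
        n_sc, n_living = count_layers(s)
        assert (m.n_corneocytes, m.n_living) == (n_sc, n_living)
        assert m.mean_living_thickness_um == pytest.approx(50.0)
        assert m.mean_sc_thickness_um == pytest.approx(20.0)
        assert m.sc_area_per100um > 0 and m.living_area_per100um > 0
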