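"""Center-based mechanics: force laws, neighbour-search equivalence, stepping."""

import dataclasses

import numpy as np
import pytest

from epidermsim import _kernels as K
from epidermsim.cell_model import Cell, CellState, LifecycleParams
from epidermsim.experiments import make_fixture
from epidermsim.geometry import MembraneSpec
from epidermsim.mechanics import (DisplacementOverflow, ForceParams, RunParams,
                                  SimConfig, SimState, _forces, initial_state,
                                  membrane_force, pairwise_force,
                                  potential_surrogate, run, step)


def sphere(i, pos, state=CellState.SPINOUS):
    return Cell(id=i, pos=np.array(pos, float), state=state)


class TestPairwiseForce:
    def test_zero_at_adhesion_cutoff(self, forces):
        ci = sphere(0, (0, 0, 0))
        cj = sphere(1, (12.0, 0, 0))  # contact 10 + adh_range 2
        np.testing.assert_allclose(pairwise_force(ci, cj, forces), 0.0)

    def test_linear_repulsion_on_overlap(self, forces):
        ci = sphere(0, (0, 0, 0))
        cj = sphere(1, (8.0, 0, 0))  # overlap 2 um
        F = pairwise_force(ci, cj, forces)
        # magnitude 2 * k_rep, directed apart (i pushed away from j)
        np.testing.assert_allclose(F, [-2.0 * forces.k_rep, 0.0, 0.0])

    def test_adhesion_pulls_at_midrange(self, forces):
        ci = sphere(0, (0, 0, 0))
        cj = sphere(1, (11.0, 0, 0))  # halfway through the adhesive shell
        F = pairwise_force(ci, cj, forces)
        # i is pulled toward j (+x) with half the contact adhesion strength
        np.testing.assert_allclose(F, [0.5 * forces.k_adh, 0.0, 0.0])

    def test_antisymmetry_over_random_pairs(self, forces, rng):
        for _ in range(1000):
            pi = rng.uniform(0, 30, 3)
            pj = pi + rng.uniform(-12, 12, 3)
            qi, qj = rng.uniform(0.2, 1.0, 2)
            ci = Cell(id=0, pos=pi, state=CellState.CORNEOCYTE,
                      a=5 * qi ** (-1 / 3), c=5 * qi ** (2 / 3))
            cj = Cell(id=1, pos=pj, state=CellState.CORNEOCYTE,
                      a=5 * qj ** (-1 / 3), c=5 * qj ** (2 / 3))
            Fij = pairwise_force(ci, cj, forces)
            Fji = pairwise_force(cj, ci, forces)
            assert np.all(Fij + Fji == 0.0)

    def test_flattened_cells_touch_farther_laterally(self, forces):
        q = 0.2
        a, c = 5 * q ** (-1 / 3), 5 * q ** (2 / 3)
        flat_i = Cell(id=0, pos=np.zeros(3), state=CellState.CORNEOCYTE, a=a, c=c)
        flat_j = Cell(id=1, pos=np.array([12.0, 0, 0]),
                      state=CellState.CORNEOCYTE, a=a, c=c)
        F = pairwise_force(flat_i, flat_j, forces)
        assert F[0] < 0  # lateral contact distance 2a > 12: still repelling
        stacked_j = Cell(id=1, pos=np.array([0, 0, 12.0]),
                         state=CellState.CORNEOCYTE, a=a, c=c)
        F = pairwise_force(flat_i, stacked_j, forces)
        np.testing.assert_allclose(F, 0.0)  # vertical contact 2c << 12

    def test_coincident_centers_finite_and_antisymmetric(self, forces):
        ci = sphere(3, (5.0, 5.0, 5.0))
        cj = sphere(9, (5.0, 5.0, 5.0))
        Fij = pairwise_force(ci, cj, forces)
        Fji = pairwise_force(cj, ci, forces)
        assert np.all(np.isfinite(Fij)) and np.linalg.norm(Fij) > 0
        np.testing.assert_array_equal(Fij, -Fji)

    def test_minimum_image_across_periodic_seam(self, forces):
        ci = sphere(0, (1.0, 50.0, 10.0))
        cj = sphere(1, (99.0, 50.0, 10.0))
        F = pairwise_force(ci, cj, forces, dom_x=100.0, dom_y=100.0)
        assert F[0] > 0  # separation is 2 um through the seam -> repulsion


class TestMembraneForce:
    def test_zero_when_clear_of_membrane(self, flat_spec, forces):
        cell = sphere(0, (50, 50, 20.0))
        np.testing.assert_allclose(membrane_force(cell, flat_spec, forces), 0.0)

    def test_repulsion_when_contacting(self, flat_spec, forces):
        cell = sphere(0, (50, 50, 3.0))  # gap 3 < c = 5
        F = membrane_force(cell, flat_spec, forces)
        np.testing.assert_allclose(F, [0, 0, forces.k_mem * 2.0])

    def test_stem_anchor_spring(self, flat_spec, forces):
        stem = Cell(id=0, pos=np.array([51.0, 50.0, 20.0]),
                    state=CellState.STEM, anchor=np.array([50.0, 50.0]))
        F = membrane_force(stem, flat_spec, forces)
        np.testing.assert_allclose(
            F, [-forces.k_anchor, 0.0, -forces.k_anchor * 20.0])


class TestGridOracle:
    def brute_force(self, state, spec, fp, lp):
        """O(N^2) all-pairs + membrane force oracle, independent of the grid."""
        cells = state.cells()
        n = len(cells)
        F = np.zeros((n, 3))
        for i in range(n):
            for j in range(n):
                if i != j:
                    F[i] += pairwise_force(cells[i], cells[j], fp,
                                           spec.domain_x_um, spec.domain_y_um)
            F[i] += membrane_force(cells[i], spec, fp)
        return F

    def test_grid_forces_match_all_pairs(self, flat_spec, forces, lifecycle):
        state = make_fixture("random_cloud", {"n": 200}, seed=1)
        F_grid, _ = _forces(state, flat_spec, forces, lifecycle)
        F_ref = self.brute_force(state, flat_spec, forces, lifecycle)
        assert np.max(np.abs(F_grid - F_ref)) < 1e-10

    def test_neighbour_counts_match_brute_force(self, flat_spec, forces,
                                                lifecycle):
        state = make_fixture("random_cloud", {"n": 150}, seed=2)
        _, nc = _forces(state, flat_spec, forces, lifecycle)
        d = state.pos[:, None, :] - state.pos[None, :, :]
        for k, L in ((0, 100.0), (1, 100.0)):
            d[..., k] -= L * np.rint(d[..., k] / L)
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        expected = np.sum(dist < 2 * lifecycle.r0_um, axis=1)
        np.testing.assert_array_equal(nc, expected)


class TestStep:
    def test_empty_state_advances_time_only(self, flat_spec, forces, lifecycle):
        state = SimState.empty(rng=np.random.default_rng(0))
        step(state, flat_spec, forces, lifecycle)
        assert state.t == pytest.approx(forces.dt_h)
        assert state.n_cells == 0

    def test_single_anchored_stem_stays_put(self, flat_spec, lifecycle):
        fp = ForceParams(noise_amp=0.0)
        state = make_fixture("single_stem", seed=0)
        state.rng = np.random.default_rng(0)
        # suppress division so the stem is alone and force-balanced
        lp = dataclasses.replace(lifecycle, division_period_h=1e12)
        p0 = state.pos.copy()
        for _ in range(200):
            step(state, flat_spec, fp, lp)
        # equilibrium on the anchor's vertical: membrane push vs anchor spring
        assert np.allclose(state.pos[0, :2], p0[0, :2], atol=1e-9)
        assert 0.0 <= state.pos[0, 2] <= lifecycle.r0_um

    def test_displacement_overflow_names_cell(self, flat_spec, lifecycle):
        fp = ForceParams(dt_h=5.0, noise_amp=0.0)  # absurd timestep
        state = make_fixture("random_cloud", {"n": 40, "zmax_um": 12.0}, seed=3)
        state.rng = np.random.default_rng(0)
        with pytest.raises(DisplacementOverflow, match="cell id"):
            for _ in range(10):
                step(state, flat_spec, fp, lifecycle)

    def test_relaxation_dissipates_overlap_energy(self, flat_spec, lifecycle):
        # pure repulsion, no noise, no lifecycle activity: the overlap +
        # penetration surrogate must not increase along the trajectory
        fp = ForceParams(k_rep=10.0, k_adh=1e-9, adh_range_um=2.0, k_mem=10.0,
                         noise_amp=0.0, dt_h=0.005)
        lp = dataclasses.replace(lifecycle, division_period_h=1e12)
        state = make_fixture("random_cloud", {"n": 60, "zmax_um": 15.0}, seed=4)
        state.rng = np.random.default_rng(0)
        e = potential_surrogate(state, flat_spec, lp)
        for _ in range(60):
            step(state, flat_spec, fp, lp)
            e_new = potential_surrogate(state, flat_spec, lp)
            assert e_new <= e + 1e-9
            e = e_new
        assert e < 0.5 * potential_surrogate(
            make_fixture("random_cloud", {"n": 60, "zmax_um": 15.0}, seed=4),
            flat_spec, lp)


class TestRun:
    def test_zero_hours_returns_initial_state_only(self):
        cfg = SimConfig(run=RunParams(t_total_h=0.0, seed=1))
        snaps = run(cfg)
        assert len(snaps) == 1
        assert snaps[0].t == 0.0
        assert np.all(snaps[0].state == int(CellState.STEM))

    def test_determinism_bitwise(self):
        cfg = SimConfig(run=RunParams(t_total_h=10.0, snapshot_every_h=5.0,
                                      seed=42))
        a = run(cfg)
        b = run(cfg)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.pos, sb.pos)
            np.testing.assert_array_equal(sa.state, sb.state)
            np.testing.assert_array_equal(sa.ids, sb.ids)
            assert (sa.births, sa.removals, sa.t) == (sb.births, sb.removals,
                                                      sb.t)

    def test_bookkeeping_identity_and_finite(self):
        cfg = SimConfig(run=RunParams(t_total_h=20.0, snapshot_every_h=5.0,
                                      seed=7))
        snaps = run(cfg)
        n_stem0 = snaps[0].n_cells
        for s in snaps:
            assert s.n_cells == s.n0 + s.births - s.removals
            assert s.counts_by_state()["STEM"] == n_stem0
            assert np.all(np.isfinite(s.pos))
            assert np.all(np.isfinite(s.aa)) and np.all(np.isfinite(s.cc))

    def test_calcium_flag_off_leaves_field_untouched(self):
        cfg = SimConfig(run=RunParams(t_total_h=5.0, snapshot_every_h=5.0,
                                      seed=3))
        snaps = run(cfg)
        assert np.all(snaps[-1].ca == 0.0)

    def test_stem_spacing_validated_against_radius(self):
        cfg = SimConfig(run=RunParams(t_total_h=1.0, stem_spacing_um=4.0))
        with pytest.raises(ValueError, match="stem_spacing"):
            initial_state(cfg)
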