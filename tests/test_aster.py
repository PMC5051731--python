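import math

import numpy as np
import pytest

import asterdrift.aster as am
from asterdrift.aster import (DI_CYTOPLASMIC, DI_STABILIZED, AsterConfig,
                              AsterSimulation, CellModel, DynamicInstability,
                              MotorParams, bending_forces, clustering_force,
                              detachment_rate, di_gradient_rates,
                              dynamic_instability_step, run_scenario,
                              sample_motor_anchors, simulate_filament_length,
                              smoke_config, solve_penta_batch, stall_velocity)
from asterdrift.fields import DriftField


@pytest.fixture
def frozen_di(monkeypatch):
    """Suppress polymerization so mechanics can be tested in isolation."""
    monkeypatch.setattr(am, "DI_CYTOPLASMIC", DynamicInstability(0, 0, 0, 0))


class TestDynamicInstability:
    def test_bounded_regime_check(self):
        di = DI_CYTOPLASMIC
        assert di.v_s * di.f_cat == pytest.approx(0.0154, abs=1e-4)
        assert di.v_g * di.f_res == pytest.approx(0.0041, abs=1e-4)
        assert di.bounded

    def test_mean_length_closed_form(self):
        assert DI_CYTOPLASMIC.mean_length() == pytest.approx(3.23, abs=0.01)
        assert DI_STABILIZED.mean_length() > DI_CYTOPLASMIC.mean_length()

    def test_deterministic_growth_without_catastrophe(self, rng):
        lengths = np.array([1.0])
        growing = np.array([True])
        for _ in range(100):
            lengths, growing = dynamic_instability_step(
                lengths, growing, 0.0, 0.0, 0.1, rng, 0.178, 0.205, 100.0)
        assert growing[0]
        assert lengths[0] == pytest.approx(1.0 + 100 * 0.1 * 0.178)

    def test_simulated_mean_matches_closed_form(self):
        sim_mean = simulate_filament_length(DI_CYTOPLASMIC, T=10000.0, dt=0.1,
                                            n_filaments=50, seed=3)
        assert sim_mean == pytest.approx(DI_CYTOPLASMIC.mean_length(), rel=0.10)


class TestMotorPrimitives:
    def test_stall_velocity_piecewise(self):
        assert stall_velocity(0.0, 7.0, 2.0) == pytest.approx(2.0)
        assert stall_velocity(-1.0, 7.0, 2.0) == pytest.approx(2.0)  # assisting
        assert stall_velocity(3.5, 7.0, 2.0) == pytest.approx(1.0)
        assert stall_velocity(7.0, 7.0, 2.0) == 0.0
        assert stall_velocity(20.0, 7.0, 2.0) == 0.0

    def test_kramers_detachment(self):
        assert detachment_rate(0.0, 1.5, 7.0) == pytest.approx(1.5)
        assert detachment_rate(7.0, 1.5, 7.0) == pytest.approx(1.5 * math.e)
        assert detachment_rate(-7.0, 1.5, 7.0) == pytest.approx(1.5 * math.e)

    def test_attachment_lifetime_decreases_with_load(self):
        # mean bound lifetime is 1/rate: monotone decreasing in |f_ex|
        loads = np.linspace(0, 14, 15)
        lifetimes = 1.0 / detachment_rate(loads, 1.5, 7.0)
        assert np.all(np.diff(lifetimes) < 0)

    def test_clustering_force_pair(self):
        fa, fb = clustering_force([0.0, 0.0], [0.0, 0.0], 100.0)
        assert np.allclose(fa, 0.0) and np.allclose(fb, 0.0)
        # heads 10 nm apart with 0.1 pN/nm stiffness: 1 pN pair force
        fa, fb = clustering_force([0.0, 0.0], [0.01, 0.0], 100.0)
        assert np.hypot(*fa) == pytest.approx(1.0)
        assert np.allclose(fa, -fb)   # equal and opposite at every step

    def test_attach_distance_gates_binding(self):
        # a motor whose anchor sits beyond d_attach never binds
        cfg = AsterConfig(scenario="uniform", n_mtoc=1, n_mt=1, T=1.0, N_mi=1,
                          seed=0, max_vertices=8, cell=CellModel(kBT=0.0))
        sim = AsterSimulation(cfg)
        sim.mtoc[0] = (20.0, 0.0)
        sim.anchor_dir[0] = (1.0, 0.0)
        sim.length[0] = 2.0
        sim.n_seg = sim._n_seg_for(sim.length)
        sim._build_straight()
        sim.anchors = np.array([[21.0, 0.05]])   # 50 nm off the filament
        from scipy import spatial
        sim._anchor_tree = spatial.cKDTree(sim.anchors)
        sim.m_fil = np.array([-1]); sim.m_absc = np.zeros(1)
        for step in range(1, 201):
            sim._refresh_neighbours(step)
            sim._motor_kinetics()
        assert sim.m_fil[0] == -1


class TestGradientMapping:
    def test_rates_at_chromatin_edge_are_stabilized(self):
        cell = CellModel()
        f_cat, f_res = di_gradient_rates(cell.r_chr, DriftField(10.0, 1.0), cell)
        assert f_cat == pytest.approx(DI_STABILIZED.f_cat, rel=1e-2)
        assert f_res == pytest.approx(DI_STABILIZED.f_res, rel=1e-2)

    def test_rates_far_away_are_cytoplasmic(self):
        cell = CellModel()
        f_cat, f_res = di_gradient_rates(39.0, DriftField(10.0, 1.0), cell)
        assert f_cat == pytest.approx(DI_CYTOPLASMIC.f_cat, rel=1e-3)

    def test_constant_field_uniform_placement(self, rng):
        cell = CellModel()
        pts = sample_motor_anchors(4000, cell, rng, None)
        r = np.hypot(pts[:, 0], pts[:, 1])
        # uniform by area: mean radius 2/3 r_cell
        assert np.mean(r) == pytest.approx(2.0 / 3.0 * cell.r_cell, rel=0.02)

    def test_gradient_placement_follows_field(self, rng):
        cell = CellModel()
        field = DriftField(10.0, 1.0)
        pts = sample_motor_anchors(10000, cell, rng, field)
        r = np.hypot(pts[:, 0], pts[:, 1])
        edges = np.arange(0, 41, 5.0)
        counts, _ = np.histogram(r, edges)
        # target mass per bin: integrate phi(r) * 2 pi r over a fine grid
        # (the sigmoid transition is steep on the bin scale)
        fine = np.linspace(0, 40.0, 8001)
        w = field.weight(np.maximum(fine - cell.r_chr, 0.0)) * 2 * math.pi * fine
        target = np.array([np.trapezoid(w[(fine >= lo) & (fine <= hi)],
                                        fine[(fine >= lo) & (fine <= hi)])
                           for lo, hi in zip(edges[:-1], edges[1:])])
        target = target / target.sum()
        observed = counts / counts.sum()
        assert np.allclose(observed, target, atol=0.02)


class TestSolver:
    def test_pentadiagonal_against_dense(self, rng):
        B, M = 5, 12
        d1 = rng.normal(size=(B, M - 1)) * 0.3
        d2 = rng.normal(size=(B, M - 2)) * 0.2
        d0 = 4.0 + np.abs(rng.normal(size=(B, M)))
        rhs = rng.normal(size=(B, M, 2))
        x = solve_penta_batch(d0, d1, d2, rhs)
        for b in range(B):
            A = (np.diag(d0[b]) + np.diag(d1[b], 1) + np.diag(d1[b], -1)
                 + np.diag(d2[b], 2) + np.diag(d2[b], -2))
            assert np.allclose(x[b], np.linalg.solve(A, rhs[b]), atol=1e-10)


class TestMechanics:
    def test_zero_temperature_zero_motor_static(self, frozen_di):
        cfg = AsterConfig(scenario="uniform", n_mtoc=3, n_mt=5, T=2.0, N_mi=0,
                          cell=CellModel(kBT=0.0), seed=1, max_vertices=10,
                          init_dn=(5.0, 15.0))
        sim = AsterSimulation(cfg)
        sim.length[:] = np.minimum(sim.length, 3.0)
        sim.n_seg = sim._n_seg_for(sim.length)
        sim._build_straight()
        v0, m0 = sim.verts.copy(), sim.mtoc.copy()
        sim.run()
        # static to accumulated floating-point roundoff (sub-nanometre)
        assert np.abs(sim.verts - v0).max() < 1e-7
        assert np.abs(sim.mtoc - m0).max() < 1e-7

    def test_straight_filament_zero_bending_force(self):
        verts = np.zeros((1, 8, 2))
        verts[0, :, 0] = np.array([0, 0.5, 1.0, 1.5, 2.0, 2.3, 2.3, 2.3])
        n_seg = np.array([5])
        rest = np.array([[0.5, 0.5, 0.5, 0.5, 0.3, 0.0, 0.0]])
        f = bending_forces(verts, n_seg, rest, 20.0)
        assert np.abs(f).max() < 1e-12

    def test_bent_filament_restoring_force(self):
        verts = np.zeros((1, 5, 2))
        verts[0, :, 0] = [0, 0.5, 1.0, 1.4, 1.4]
        verts[0, 3, 1] = 0.3    # kink at vertex 2-3
        n_seg = np.array([3])
        rest = np.array([[0.5, 0.5, 0.5, 0.0]])
        f = bending_forces(verts, n_seg, rest, 20.0)
        assert np.abs(f).max() > 0.1
        # bending is internal: zero net force on the filament
        assert np.allclose(f.sum(axis=1), 0.0, atol=1e-9)

    def test_contour_length_conserved_by_mechanics(self):
        cfg = smoke_config("motor_gradient", seed=2, T=2.0, n_mtoc=3)
        sim = AsterSimulation(cfg)
        sim.run()
        rest = sim._rest_lengths()
        d = sim.verts[:, 1:] - sim.verts[:, :-1]
        geom = np.hypot(d[:, :, 0], d[:, :, 1])
        idx = np.arange(sim.M - 1)
        active = idx[None, :] < sim.n_seg[:, None]
        assert np.abs((geom - rest)[active]).max() < 1e-9

    def test_free_mtoc_diffusion_einstein_relation(self):
        # no filaments: the body diffuses with D = kBT / (6 pi eta r)
        cfg = AsterConfig(scenario="uniform", n_mtoc=300, n_mt=0, T=10.0,
                          N_mi=0, seed=2, record_interval=1.0)
        res = run_scenario(cfg)
        pos = np.stack([t.positions for t in res["trajectories"]])
        disp2 = np.sum((pos[:, 1:] - pos[:, :-1]) ** 2, axis=-1)
        D_fit = float(np.mean(disp2)) / 4.0
        cell = cfg.cell
        D_expect = cell.kBT / (6 * math.pi * cell.eta * cfg.mtoc_radius)
        assert D_fit == pytest.approx(D_expect, rel=0.15)

    def test_cortical_pushing_moves_filament_base_inward(self, frozen_di,
                                                         monkeypatch):
        # growth-only single filament pressed against the cortex pushes its
        # MTOC away from the boundary (rigid-rod oracle behaviour), until
        # buckling stalls it
        monkeypatch.setattr(am, "DI_CYTOPLASMIC",
                            DynamicInstability(0.178, 0.0, 0.0, 0.0))
        cfg = AsterConfig(scenario="uniform", n_mtoc=1, n_mt=1, T=30.0, N_mi=0,
                          cell=CellModel(kBT=0.0), seed=11, max_vertices=16)
        sim = AsterSimulation(cfg)
        sim.mtoc[0] = (38.0, 0.0)
        sim.anchor_dir[0] = (1.0, 0.0)
        sim.length[0] = 1.0
        sim.n_seg = sim._n_seg_for(sim.length)
        sim._build_straight()
        sim.run()
        assert sim.mtoc[0, 0] < 37.6

    def test_two_aster_coalescence_with_crosslinkers(self):
        # clustering oracle: complexes pre-bound at filament crossings walk
        # minus-ward and pull the two asters together
        cfg = AsterConfig(scenario="clustering", n_mtoc=2, n_mt=12, T=20.0,
                          N_mi=0, N_mc=60, seed=7, max_vertices=12,
                          record_interval=2.0, cell=CellModel(kBT=1e-4))
        sim = AsterSimulation(cfg)
        sim.mtoc[0] = (-2.0, 0.0)
        sim.mtoc[1] = (2.0, 0.0)
        sim.length[:] = 3.5
        sim.n_seg = sim._n_seg_for(sim.length)
        sim._build_straight()
        placed = 0
        rest = sim._rest_lengths()
        for fa in range(cfg.n_mt):
            for fb in range(cfg.n_mt, 2 * cfg.n_mt):
                for ia in range(sim.n_seg[fa]):
                    for ib in range(sim.n_seg[fb]):
                        p1, p2 = sim.verts[fa, ia], sim.verts[fa, ia + 1]
                        q1, q2 = sim.verts[fb, ib], sim.verts[fb, ib + 1]
                        d1, d2 = p2 - p1, q2 - q1
                        den = d1[0] * d2[1] - d1[1] * d2[0]
                        if abs(den) < 1e-12:
                            continue
                        t = ((q1[0] - p1[0]) * d2[1] - (q1[1] - p1[1]) * d2[0]) / den
                        s = ((q1[0] - p1[0]) * d1[1] - (q1[1] - p1[1]) * d1[0]) / den
                        if 0 <= t <= 1 and 0 <= s <= 1 and placed < cfg.N_mc:
                            sim.c_fil[placed] = (fa, fb)
                            sim.c_absc[placed] = (ia * 0.5 + t * rest[fa, ia],
                                                  ib * 0.5 + s * rest[fb, ib])
                            placed += 1
        assert placed >= 4
        d_start = float(np.hypot(*(sim.mtoc[0] - sim.mtoc[1])))
        sim.run()
        d_end = float(np.hypot(*(sim.mtoc[0] - sim.mtoc[1])))
        assert d_end < d_start - 0.1


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            AsterConfig(scenario="warp_drive")

    @pytest.mark.parametrize("scenario", ["di_gradient", "hybrid", "clustering"])
    def test_all_scenarios_execute(self, scenario):
        cfg = smoke_config(scenario, seed=3, T=2.0, n_mtoc=2, N_mi=50, N_mc=50)
        res = run_scenario(cfg)
        assert len(res["trajectories"]) == 2
        assert res["rejected_steps"] == 0

    def test_run_scenario_outputs(self):
        cfg = smoke_config("uniform", seed=1, T=5.0, n_mtoc=4)
        res = run_scenario(cfg)
        assert len(res["trajectories"]) == 4
        assert 0.0 <= res["capture_fraction"] <= 1.0
        for tr in res["trajectories"]:
            assert len(tr) >= 1
            assert tr.d_n >= 0.0

    def test_seed_determinism(self):
        a = run_scenario(smoke_config("motor_gradient", seed=5, T=3.0, n_mtoc=3))
        b = run_scenario(smoke_config("motor_gradient", seed=5, T=3.0, n_mtoc=3))
        for ta, tb in zip(a["trajectories"], b["trajectories"]):
            assert np.array_equal(ta.positions, tb.positions)
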