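import numpy as np
import pytest

import mtconfine as mc
from mtconfine.simulator import grow_tip, nucleate, shrink_tip, step
from mtconfine.state import GROWING, SHRINKING

from conftest import quiet_params, seed_mt


def _all_vertices(state):
    return np.vstack([mt.as_array() for mt in state.mts.values()])


class TestNucleate:
    def test_zero_rate_no_op(self, rect_box):
        p = quiet_params()
        state = mc.new_state(rect_box, p)
        nucleate(state, p, np.random.default_rng(0))
        assert len(state.mts) == 0

    def test_poisson_moments(self, rect_box):
        """Counts over 1,000 draws follow Poisson(k_nuc): mean ~ 2,000,
        SD ~ sqrt(2000)."""
        p = quiet_params(k_nuc=2.0)
        state = mc.new_state(rect_box, p)
        rng = np.random.default_rng(5)
        for _ in range(1000):
            nucleate(state, p, rng)
        n = state.counters["nucleated"]
        assert abs(n - 2000) < 4 * np.sqrt(2000)

    def test_new_mts_have_one_element_inside(self, sphere10):
        p = quiet_params(k_nuc=5.0)
        state = mc.new_state(sphere10, p)
        rng = np.random.default_rng(6)
        for _ in range(50):
            nucleate(state, p, rng)
        for mt in state.mts.values():
            assert mt.n_elements == 1
            assert mt.plus_state == GROWING
            v = mt.as_array()
            assert sphere10.contains_many(v).all()
            assert np.linalg.norm(v[1] - v[0]) == pytest.approx(0.2,
                                                                abs=1e-9)

    def test_surface_mode_first_vertex_on_membrane(self, sphere10):
        p = quiet_params(k_nuc=5.0, nucleation_mode="surface")
        state = mc.new_state(sphere10, p)
        rng = np.random.default_rng(7)
        for _ in range(50):
            nucleate(state, p, rng)
        assert len(state.mts) > 100
        for mt in state.mts.values():
            v = mt.as_array()
            assert np.linalg.norm(v[0]) == pytest.approx(10.0, abs=1e-9)
            assert sphere10.contains_many(v).all()
            assert np.linalg.norm(v[1] - v[0]) == pytest.approx(0.2,
                                                                abs=1e-9)


class TestGrowShrink:
    def test_lone_tip_extends(self, rect_box):
        p = quiet_params()
        state = mc.new_state(rect_box, p)
        mt = seed_mt(state, (0, 0, 0), (1, 0, 0))
        assert grow_tip(mt, state, p, np.random.default_rng(0)) == "extended"
        assert mt.n_elements == 2
        assert mt.vertices[-1] == pytest.approx((0.4, 0, 0))

    def test_head_on_edge_catastrophe(self, rect_box):
        p = quiet_params(p_edge_cat=1.0)
        state = mc.new_state(rect_box, p)
        mt = seed_mt(state, (19.5, 0, 0), (1, 0, 0), n_elements=2)
        ev = grow_tip(mt, state, p, np.random.default_rng(0))
        assert ev == "boundary_catastrophe"
        assert mt.plus_state == SHRINKING

    def test_grazing_deflection_is_tangential(self, rect_box):
        # tip heading 10 degrees above the +z face plane: deflected
        # direction is the in-plane projection of the heading
        import math
        inc = math.radians(10)
        d = (math.cos(inc), 0.0, math.sin(inc))
        p = quiet_params(theta_edge=45.0)
        state = mc.new_state(rect_box, p)
        ell = 0.2
        tip0 = (0.0, 0.0, 7.48)
        start = (tip0[0] - ell * d[0], tip0[1] - ell * d[1],
                 tip0[2] - ell * d[2])
        mt = state.add_mt([start, tip0], d)
        ev = grow_tip(mt, state, p, np.random.default_rng(0))
        assert ev == "boundary_deflected"
        assert mt.plus_dir == pytest.approx((1.0, 0.0, 0.0), abs=1e-9)
        assert np.linalg.norm(mt.plus_dir) == pytest.approx(1.0, abs=1e-12)

    def test_shrink_removes_one_element(self, rect_box):
        p = quiet_params()
        state = mc.new_state(rect_box, p)
        mt = seed_mt(state, (0, 0, 0), (1, 0, 0), n_elements=5,
                     plus_state=SHRINKING)
        assert shrink_tip(mt, state, p) == "shortened"
        assert mt.n_elements == 4

    def test_last_element_death_clears_records(self, rect_box):
        p = quiet_params()
        state = mc.new_state(rect_box, p)
        host = seed_mt(state, (0, 1, 0), (0, 1, 0), n_elements=3)
        mt = seed_mt(state, (0, 0, 0), (1, 0, 0), plus_state=SHRINKING)
        rec = state.add_crossover(mt.id, 0, host.id)
        assert shrink_tip(mt, state, p) == "died"
        assert mt.id not in state.mts
        assert not rec.alive

    def test_forced_rescue_preserves_length(self, rect_box):
        p = quiet_params(t_steps=1, p_rescue=1.0)
        state = mc.new_state(rect_box, p)
        mt = seed_mt(state, (0, 0, 0), (1, 0, 0), n_elements=5,
                     plus_state=SHRINKING)
        step(state, p, np.random.default_rng(0))
        assert mt.plus_state == GROWING
        assert mt.n_elements == 6  # rescued before removal, then grew


class TestStep:
    def test_empty_quiet_step_only_advances_counter(self, rect_box):
        p = quiet_params()
        empty = mc.new_state(rect_box, p)
        step(empty, p, np.random.default_rng(0))
        assert empty.step == 1 and len(empty.mts) == 0

    def test_deterministic_trajectories(self, rect_box):
        p = mc.SimulationParams(t_steps=200, seed=11, r_replicates=1)
        a = mc.run(p, rect_box).final_state
        b = mc.run(p, rect_box).final_state
        pa, pb = a.polylines(), b.polylines()
        assert len(pa) == len(pb)
        for (ia, va, sa), (ib, vb, sb) in zip(pa, pb):
            assert ia == ib and sa == sb
            assert np.array_equal(va, vb)

    def test_growth_phase_lifetime_geometric(self, sphere10):
        """With catastrophe probability p per step and no rescue, growth
        phases last 1/p = 100 steps on average."""
        # domain large enough that no tip can reach the membrane within
        # the simulated horizon, isolating the spontaneous transitions
        big = mc.make_domain("sphere", radius=400)
        p = quiet_params(p_spont_cat=0.01, d_contact=0.01)
        state = mc.new_state(big, p)
        rng = np.random.default_rng(12)
        n_mt = 800
        for i in range(n_mt):
            pt = rng.uniform(-6, 6, 3)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            seed_mt(state, pt, v)
        for _ in range(1500):
            step(state, p, rng)
        completed = n_mt - sum(mt.plus_state == GROWING
                               for mt in state.mts.values())
        mean_life = state.counters["extended"] / completed
        se = 100.0 / np.sqrt(completed)
        assert abs(mean_life - 100.0) < 4 * se

    def test_polymer_growth_exact_without_interactions(self):
        """With all transitions and interactions off, total length grows
        by one element per growing MT per step, exactly."""
        big = mc.make_domain("box", lx=200, ly=200, lz=200)
        p = quiet_params()
        state = mc.new_state(big, p)
        rng = np.random.default_rng(13)
        for i in range(20):
            seed_mt(state, (-80 + 8 * i, -80 + 8 * i, 0), (0, 0, 1))
        for k in range(50):
            step(state, p, rng)
        assert state.total_elements() == 20 + 20 * 50

    def test_confinement_and_element_length_full_run(self, rect_box):
        p = mc.SimulationParams(t_steps=400, seed=3, r_replicates=1)
        state = mc.run(p, rect_box).final_state
        pts = _all_vertices(state)
        assert rect_box.contains_many(pts).all()
        for mt in state.mts.values():
            v = mt.as_array()
            lens = np.linalg.norm(np.diff(v, axis=0), axis=1)
            assert np.allclose(lens, 0.2, atol=1e-9)

    def test_spatial_index_consistent_after_run(self, square_box):
        p = mc.SimulationParams(t_steps=150, seed=4, r_replicates=1)
        state = mc.run(p, square_box).final_state
        entries = list(state.iter_entries())
        assert len(entries) == state.total_elements()
        refs = {id(e) for mt in state.mts.values() for e in mt.grid_refs}
        assert {id(e) for e in entries} == refs

    def test_replicates_distinct_and_reproducible(self, square_box):
        p = mc.SimulationParams(t_steps=60, seed=21, r_replicates=3)
        runs = mc.run_replicates(p, square_box)
        assert [r.seed for r in runs] == [21, 22, 23]
        assert len({r.final_state.total_elements() for r in runs}) > 1
        again = mc.run(p, square_box, seed=22).final_state
        assert again.total_elements() == runs[1].final_state.total_elements()

    def test_zero_steps_initial_state(self, square_box):
        p = quiet_params(t_steps=0)
        summary = mc.run(p, square_box)
        assert summary.final_state.step == 0
        assert len(summary.final_state.mts) == 0
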