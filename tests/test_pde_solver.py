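"""Solver mechanics: initialization, stability bound, conservation, oracles."""

import numpy as np
import pytest
from scipy.special import erfc

from aeroband.core_model import ModelParameters, SpatialGrid
from aeroband.pde_solver import (
    SimulationState,
    SolverInstabilityError,
    _advect_upwind,
    advect_react_step,
    diffuse_consume_step,
    initialize,
    run_simulation,
    stable_dt,
)

P = ModelParameters()
G = SpatialGrid.from_cells_per_mm(P.S, 128)


class TestInitialize:
    def test_uniform_oxygen_free_start(self):
        st = initialize(P, G)
        assert st.t == 0.0
        np.testing.assert_allclose(st.B, P.B_o)
        np.testing.assert_array_equal(st.R - st.L, 0.0)
        np.testing.assert_array_equal(st.C, 0.0)
        # total bacteria per unit cross-section
        assert np.sum(st.B) * G.dx == pytest.approx(P.B_o * P.S)


class TestStableDt:
    def test_diffusive_bound_binds_for_base_parameters(self):
        # dx = 7.8125 μm: advective bound 0.390625 s, diffusive ~0.015259 s
        assert G.dx == pytest.approx(7.8125)
        assert stable_dt(P, G, safety=1.0) == pytest.approx(G.dx**2 / (2 * P.D))
        assert stable_dt(P, G, safety=1.0) == pytest.approx(0.0152587890625)

    def test_advective_bound_binds_for_slow_diffusion(self):
        q = P.replace(D=1.0)
        assert stable_dt(q, G, safety=1.0) == pytest.approx(G.dx / q.v)

    def test_doubling_D_halves_dt_when_diffusion_limited(self):
        assert stable_dt(P.replace(D=4000.0), G, 1.0) == pytest.approx(
            stable_dt(P, G, 1.0) / 2
        )

    def test_safety_validated(self):
        with pytest.raises(ValueError):
            stable_dt(P, G, safety=0.0)
        with pytest.raises(ValueError):
            stable_dt(P, G, safety=1.5)


class TestAdvection:
    def test_pulse_moves_one_cell_per_step_at_unit_courant(self):
        # pure upwind transport at CFL = 1 is exact shift-by-one
        R = np.zeros(G.n_cells)
        L = np.zeros(G.n_cells)
        R[10] = 1.0
        dt = G.dx / P.v
        Rn, Ln = _advect_upwind(R, L, P.v, dt, G)
        assert Rn[11] == pytest.approx(1.0)
        assert Rn.sum() + Ln.sum() == pytest.approx(1.0)
        assert np.count_nonzero(Rn) == 1 and np.count_nonzero(Ln) == 0

    def test_walls_reflect_into_opposite_population(self):
        R = np.zeros(G.n_cells)
        L = np.zeros(G.n_cells)
        R[-1] = 1.0  # right-movers at the sealed end turn left
        dt = G.dx / P.v
        Rn, Ln = _advect_upwind(R, L, P.v, dt, G)
        assert Ln[-1] == pytest.approx(1.0) and Rn.sum() == pytest.approx(0.0)
        L2 = np.zeros(G.n_cells)
        L2[0] = 1.0  # left-movers at the meniscus turn right
        Rn, Ln = _advect_upwind(np.zeros(G.n_cells), L2, P.v, dt, G)
        assert Rn[0] == pytest.approx(1.0) and Ln.sum() == pytest.approx(0.0)

    def test_uniform_state_with_equal_frequencies_is_fixed_point(self):
        # C above the detectable range: both directions reverse at F_min,
        # reactions balance and wall fluxes cancel
        st = initialize(P, G)
        st.C[:] = P.C_o_uM  # 21% > C_hat_max
        R, L = advect_react_step(st, None, P, G, dt=0.01)
        np.testing.assert_allclose(R, P.B_o / 2, rtol=1e-14)
        np.testing.assert_allclose(L, P.B_o / 2, rtol=1e-14)

    def test_mass_conserved_per_step_with_band_and_gradient(self):
        rng = np.random.default_rng(42)
        st = initialize(P, G)
        st.R += rng.uniform(0, 0.3 * P.B_o, G.n_cells)
        st.L += rng.uniform(0, 0.3 * P.B_o, G.n_cells)
        st.C = np.linspace(P.C_o_uM, 0.0, G.n_cells)
        total0 = st.B.sum()
        for _ in range(50):
            st.R, st.L = advect_react_step(st, (300.0, 500.0), P, G, dt=0.0137)
        assert st.B.sum() == pytest.approx(total0, rel=1e-12)

    def test_cfl_violation_raises(self):
        st = initialize(P, G)
        st.R[5] = 100 * P.B_o  # sharp spike + huge dt drives negativity
        with pytest.raises(SolverInstabilityError):
            advect_react_step(st, None, P, G, dt=10 * G.dx / P.v)


class TestOxygen:
    def test_pure_diffusion_matches_erfc_solution(self):
        # with no bacteria the PDE is the heat equation on a half line until
        # the sealed far wall is felt: C = C_o erfc(x / (2 sqrt(D t)))
        st = initialize(P, G)
        st.R[:] = 0.0
        st.L[:] = 0.0
        dt = stable_dt(P, G, 0.9)
        t = 0.0
        while t < 50.0 - 1e-9:
            step = min(dt, 50.0 - t)
            st.C = diffuse_consume_step(st, P, G, step)
            t += step
        exact = P.C_o_uM * erfc(G.centers / (2 * np.sqrt(P.D * t)))
        near = G.centers < G.S / 2
        err = np.abs(st.C[near] - exact[near])
        assert err.max() <= 0.01 * P.C_o_uM

    def test_saturated_profile_without_consumers_is_steady(self):
        st = initialize(P, G)
        st.R[:] = 0.0
        st.L[:] = 0.0
        st.C[:] = P.C_o_uM
        Cn = diffuse_consume_step(st, P, G, stable_dt(P, G, 0.9))
        np.testing.assert_allclose(Cn, P.C_o_uM, rtol=1e-14)

    def test_no_consumption_in_depleted_cells(self):
        # interior cells with C = 0 stay at 0 despite dense bacteria
        st = initialize(P, G)
        st.R[:] = 10 * P.B_o
        Cn = diffuse_consume_step(st, P, G, stable_dt(P, G, 0.9))
        assert np.all(Cn[1:] == 0.0)
        assert Cn[0] > 0.0  # boundary influx only

    def test_consumption_clamped_to_available_oxygen(self):
        st = initialize(P, G)
        st.C[:] = 1e-6  # far less than one step's demand K*B*dt
        Cn = diffuse_consume_step(st, P, G, stable_dt(P, G, 0.9))
        assert np.all(Cn >= 0.0)


class TestRunSimulation:
    def test_validates_times(self):
        with pytest.raises(ValueError):
            run_simulation(P, G, t_end=-1.0)
        with pytest.raises(ValueError):
            run_simulation(P, G, t_end=10.0, output_times=[0.0, 20.0])

    def test_short_run_hits_output_times_exactly(self):
        res = run_simulation(P, G, t_end=2.0, output_times=[0.0, 0.5, 2.0])
        assert [s.t for s in res.snapshots] == [0.0, 0.5, 2.0]
        assert res.band_trace.times[0] == 0.0
        assert res.band_trace.times[-1] == pytest.approx(2.0)

    def test_base_run_conserves_mass_and_respects_bounds(self, base_case):
        result, _ = base_case
        assert result.conservation_error < 1e-9
        p = result.params
        for snap in result.snapshots:
            assert np.all(snap.R >= 0) and np.all(snap.L >= 0)
            assert np.all(snap.C >= 0) and np.all(snap.C <= p.C_o_uM * (1 + 1e-12))

    def test_base_band_steady_between_300_and_600s(self, base_case):
        result, _ = base_case
        tr = result.band_trace
        drift = abs(tr.at_time(600.0)["location"] - tr.at_time(300.0)["location"])
        assert drift < 5.0

    def test_grid_refinement_shifts_location_under_3pct(self, base_case):
        result, _ = base_case
        loc640 = result.band_trace.at_time(300.0)["location"]
        fine = SpatialGrid.from_cells_per_mm(P.S, 256)
        res2 = run_simulation(P, fine, 300.0, [0.0, 300.0])
        loc1280 = res2.band_trace.at_time(300.0)["location"]
        assert abs(loc1280 - loc640) / loc640 < 0.03
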