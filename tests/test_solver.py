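"""Solver tests: stability bounds, scheme oracles, conservation, splitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from dataclasses import replace

import jnktransport as jt
from jnktransport.registry import SPECIES
from jnktransport.solver import SolverError


def gaussian(x, mu, sd):
    return np.exp(-((x - mu) ** 2) / (2 * sd**2))


class TestStableDt:
    @pytest.mark.parametrize(
        "dx,d_max,v,safety,expected",
        [
            (0.5, 10.0, 0.0, 1.0, 0.0125),  # diffusive bound dx^2/(2D)
            (0.5, 0.0, 1.0, 1.0, 0.5),  # CFL bound dx/v
            (0.5, 10.0, 1.0, 0.4, 0.005),  # min of both, scaled
        ],
    )
    def test_bounds(self, dx, d_max, v, safety, expected):
        grid = jt.Grid1D(L=dx * 100, n_cells=100)
        params = jt.TransportParams(v=v, safety=safety)
        assert jt.stable_dt(grid, params, d_max) == pytest.approx(expected)

    def test_no_transport_is_an_error(self, grid):
        with pytest.raises(ValueError):
            jt.stable_dt(grid, jt.TransportParams(v=0.0), 0.0)


class TestDiffusionStep:
    def test_uniform_field_unchanged(self, grid):
        field = np.full(grid.n_cells, 3.7)
        out = jt.diffusion_step(field, grid, 0.01, 10.0)
        assert np.allclose(out, field, atol=1e-14)

    def test_mass_conserved_exactly(self, grid):
        rng = np.random.default_rng(42)
        field = rng.uniform(0, 5, grid.n_cells)
        out = jt.diffusion_step(field, grid, 0.01, 10.0)
        assert out.sum() * grid.dx == pytest.approx(field.sum() * grid.dx, rel=1e-14)

    def test_unstable_dt_rejected(self, grid):
        with pytest.raises(SolverError):
            jt.diffusion_step(np.ones(grid.n_cells), grid, 1.0, 10.0)

    def test_gaussian_variance_grows_2dt_per_step(self, grid):
        """FTCS tracks the heat kernel: Var grows by 2 D dt per step."""
        D, dt = 10.0, 0.01
        x = grid.cell_centers
        field = gaussian(x, 50.0, 3.0)
        n_steps = 100
        for _ in range(n_steps):
            field = jt.diffusion_step(field, grid, dt, D)
        m = field.sum()
        mu = (x * field).sum() / m
        var = ((x - mu) ** 2 * field).sum() / m
        assert var == pytest.approx(3.0**2 + 2 * D * dt * n_steps, rel=0.01)

    def test_second_order_convergence_vs_heat_kernel(self):
        """L2 error vs the analytic kernel shrinks ~O(dx^2) at fixed dt/dx^2."""
        D, t_final, sd0 = 10.0, 1.0, 3.0
        errs = []
        for n in (100, 200, 400):
            grid = jt.Grid1D(L=100.0, n_cells=n)
            r = 0.2  # dt = r dx^2 / D
            dt = r * grid.dx**2 / D
            steps = int(round(t_final / dt))
            x = grid.cell_centers
            field = gaussian(x, 50.0, sd0)
            for _ in range(steps):
                field = jt.diffusion_step(field, grid, dt, D)
            t = steps * dt
            sd_t = np.sqrt(sd0**2 + 2 * D * t)
            exact = (sd0 / sd_t) * gaussian(x, 50.0, sd_t)
            errs.append(np.sqrt(np.mean((field - exact) ** 2)))
        assert errs[0] / errs[1] > 3.0  # ~4x per refinement for O(dx^2)
        assert errs[1] / errs[2] > 3.0


class TestAdvectionStep:
    def test_zero_field_stays_zero(self, grid):
        out = jt.advection_step(np.zeros(grid.n_cells), grid, 0.1, 1.0)
        assert np.all(out == 0)

    def test_courant_above_one_rejected(self, grid):
        with pytest.raises(SolverError):
            jt.advection_step(np.ones(grid.n_cells), grid, 1.0, 1.0)  # c = 2

    @pytest.mark.parametrize("limiter", [False, True])
    def test_exact_shift_at_unit_courant(self, grid, limiter):
        """At c = 1 the scheme reduces to an exact one-cell shift."""
        x = grid.cell_centers
        field = gaussian(x, 30.0, 2.0)
        v = 1.0
        dt = grid.dx / v
        out = jt.advection_step(field, grid, dt, v, limiter=limiter)
        expected = np.concatenate([[0.0], field[:-1]])
        expected[-1] += field[-1]  # closed outflow accumulates
        assert np.allclose(out, expected, atol=1e-13)

    @pytest.mark.parametrize("limiter", [False, True])
    def test_centroid_speed_at_half_courant(self, grid, limiter):
        """Pulse centroid advances by v t within 1% over 200 steps."""
        x = grid.cell_centers
        field = gaussian(x, 20.0, 2.0)
        v = 1.0
        dt = 0.5 * grid.dx / v
        for _ in range(200):
            field = jt.advection_step(field, grid, dt, v, limiter=limiter)
        mu0, mu = 20.0, (x * field).sum() / field.sum()
        assert mu - mu0 == pytest.approx(v * 200 * dt, rel=0.01)

    def test_mass_conserved_and_limiter_positive(self, grid):
        x = grid.cell_centers
        field = np.where(np.abs(x - 10) < 1, 5.0, 0.0)  # sharp pulse
        v, dt = 1.0, 0.05
        plain = lim = field.copy()
        for _ in range(400):
            plain = jt.advection_step(plain, grid, dt, v, limiter=False)
            lim = jt.advection_step(lim, grid, dt, v, limiter=True)
        for out in (plain, lim):
            assert out.sum() * grid.dx == pytest.approx(field.sum() * grid.dx, rel=1e-12)
        assert lim.min() >= -1e-14  # TVD scheme does not undershoot
        assert plain.min() < -1e-6  # the plain scheme does, on sharp data


class TestRunSimulation:
    def test_no_scaffold_no_motor_keeps_all_kif5_complexes_zero(self):
        sc = jt.default_scenario(0.0, 0.0, n_cells=60, L=100.0, t_end=50)
        kymo = jt.run_simulation(sc)
        for name in SPECIES:
            if "KIF5-" in name or "JIP1" in name:
                idx = kymo.species_index(name)
                assert np.all(kymo.conc[idx] == 0.0), name

    def test_moiety_conservation_with_transport(self):
        sc = jt.default_scenario(1.0, 5.0, n_cells=80, L=100.0, t_end=400)
        kymo = jt.run_simulation(sc)
        totals = kymo.moiety_totals()
        scale = np.abs(totals[0]).max()
        assert np.abs(totals - totals[0]).max() / scale < 1e-9

    def test_well_mixed_matches_reference_ode(self, constants):
        """Uniform state, v = 0: every cell follows the reaction ODE."""
        amps = dict(zip(SPECIES, [1.0, 0.5, 0.3, 0.0, 0.1, 0, 0, 0, 0, 0, 0.5, 0, 0, 0, 0]))
        sc = jt.default_scenario(0, 0, n_cells=20, L=100.0)
        sc = replace(
            sc,
            profiles={n: jt.InitialProfile("uniform", a) for n, a in amps.items()},
        )
        kymo = jt.run_simulation(sc, t_end=1000, record_every=100)
        sol = solve_ivp(
            lambda t, y: jt.reaction_rhs(np.maximum(y, 0), constants),
            (0, 1000),
            sc.initial_state()[:, 0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-13,
            t_eval=kymo.times,
        )
        scale = np.abs(sol.y).max()
        err = np.abs(kymo.conc[:, :, :] - sol.y[:, :, None]).max() / scale
        assert err < 1e-4
        # all cells identical (diffusion of a uniform field is a no-op)
        assert np.ptp(kymo.conc, axis=2).max() == 0.0

    def test_zero_motor_runs_are_independent_of_the_advection_path(self):
        """v = 0 results are bitwise equal with and without the limiter."""
        sc = jt.default_scenario(1.0, 0.0, n_cells=40, L=100.0, t_end=20)
        a = jt.run_simulation(sc)
        b = jt.run_simulation(sc, limiter=not sc.transport.limiter)
        assert np.array_equal(a.conc, b.conc)
        assert np.array_equal(a.series, b.series)

    def test_one_step_matches_manual_operator_splitting(self, constants):
        """The compiled kernel agrees with composing the public steps."""
        sc = jt.default_scenario(1.0, 5.0, n_cells=30, L=100.0, series_every=1.0)
        kymo = jt.run_simulation(sc, t_end=1.0, record_every=1.0)
        dt = kymo.dt
        steps = int(round(1.0 / dt))
        state = sc.initial_state().copy()
        reg = sc.registry
        dcoef = reg.diffusion_array(sc.diffusion)
        v = sc.transport.v
        for _ in range(steps):
            r1 = jt.reaction_rhs(state, constants)
            r2 = jt.reaction_rhs(np.maximum(state + dt * r1, 0), constants)
            state = state + 0.5 * dt * (r1 + r2)
            for i in range(15):
                if dcoef[i] > 0:
                    state[i] = jt.diffusion_step(state[i], sc.grid, dt, dcoef[i])
                elif reg.mobility[i] == "advective":
                    state[i] = jt.advection_step(
                        state[i], sc.grid, dt, v, limiter=sc.transport.limiter
                    )
            state = np.maximum(state, 0.0)
        assert np.allclose(kymo.conc[:, -1, :], state, rtol=1e-10, atol=1e-12)

    def test_halving_dt_barely_changes_peripheral_series(self):
        """Splitting error: halving dt moves peripheral JNK* by < 0.5%."""
        sc = jt.default_scenario(1.0, 5.0, n_cells=60, L=100.0, t_end=300)
        coarse = jt.run_simulation(sc)
        fine = jt.run_simulation(replace(sc, transport=replace(sc.transport, safety=0.4)))
        scale = fine.series.max()
        assert np.abs(coarse.series - fine.series).max() / scale < 0.005

    def test_negative_time_horizon_rejected(self):
        sc = jt.default_scenario(0, 0, n_cells=20, L=100.0)
        with pytest.raises(ValueError):
            jt.run_simulation(sc, t_end=0.0)
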