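"""The explicit finite-difference drying solver and its analytic oracle."""

import numpy as np
import pytest

from capsuledry import (
    ConfigError,
    DeffParams,
    DryingConditions,
    MoistureField,
    SolverOptions,
    StabilityError,
    analytic_slab_ratio,
    average_moisture,
    build_grid,
    deff_avg,
    effective_diffusivity,
    simulate,
    stable_timestep,
    step_constant,
    step_variable,
)
from capsuledry.errors import NumericalError

COND = DryingConditions(35.0, 60.0, 0.1)


class TestGrid:
    @pytest.mark.parametrize(
        "length,z,dl",
        [(2e-4, 4, 5e-5), (1.0, 2, 0.5), (2e-4, 64, 3.125e-6)],
    )
    def test_spacing(self, length, z, dl):
        g = build_grid(length, z)
        assert g.spacing == pytest.approx(dl, rel=1e-15)
        assert g.n_nodes == z + 1
        assert g.node_positions[0] == 0.0
        assert g.node_positions[-1] == pytest.approx(length)

    @pytest.mark.parametrize("length,z", [(2e-4, 1), (2e-4, 0), (0.0, 4), (-1.0, 4)])
    def test_invalid_grid(self, length, z):
        with pytest.raises(ConfigError):
            build_grid(length, z)


class TestStableTimestep:
    def test_printed_bound(self):
        # dl^2/(6 D) = (5e-5)^2 / (6 * 5e-10), by hand
        g = build_grid(2e-4, 4)
        assert stable_timestep(g, 5e-10, 1.0) == pytest.approx(0.8333333333333333)

    def test_safety_scales_linearly(self):
        g = build_grid(2e-4, 4)
        assert stable_timestep(g, 5e-10, 0.9) == pytest.approx(0.75)

    def test_halving_spacing_quarters_step(self):
        a = stable_timestep(build_grid(2e-4, 4), 5e-10)
        b = stable_timestep(build_grid(2e-4, 8), 5e-10)
        assert b == pytest.approx(a / 4.0)


def _uniform_field(grid, value, m_e=None):
    v = np.full(grid.n_nodes, value)
    if m_e is not None:
        v[-1] = m_e
    return MoistureField(grid, 0.0, v)


class TestSteps:
    grid = build_grid(2e-4, 4)
    params = DeffParams(D0=1e-6, Ea=3e4, a=0.2, b=0.05)

    def test_equilibrium_is_a_fixed_point(self):
        f = _uniform_field(self.grid, COND.equilibrium_moisture)
        dt = stable_timestep(self.grid, 1e-10, 0.9)
        for _ in range(5):
            f = step_variable(f, self.params, COND, dt)
        np.testing.assert_allclose(f.values, COND.equilibrium_moisture, rtol=1e-14)

    def test_interior_nodes_non_increasing_from_uniform_wet_state(self):
        f = _uniform_field(self.grid, 8.44, m_e=0.1)
        d = np.max(effective_diffusivity(self.params, f.values, COND.temperature_k))
        g = step_variable(f, self.params, COND, stable_timestep(self.grid, d, 0.9))
        assert np.all(g.values <= f.values + 1e-15)

    def test_uniform_diffusivity_reduces_to_constant_stencil(self):
        rng = np.random.default_rng(7)
        vals = np.sort(rng.uniform(0.1, 8.0, self.grid.n_nodes))[::-1].copy()
        vals[-1] = COND.equilibrium_moisture
        p0 = DeffParams(D0=4e-11, Ea=0.0, a=0.0, b=0.0)
        dt = stable_timestep(self.grid, 4e-11, 0.9)
        a = step_variable(MoistureField(self.grid, 0.0, vals.copy()), p0, COND, dt)
        b = step_constant(MoistureField(self.grid, 0.0, vals.copy()), 4e-11, COND, dt)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-14)

    def test_stability_violation_refuses_to_step(self):
        f = _uniform_field(self.grid, 8.44, m_e=0.1)
        bound = stable_timestep(self.grid, 5e-10, 1.0)
        with pytest.raises(StabilityError):
            step_constant(f, 5e-10, COND, 2.0 * bound)

    def test_two_half_steps_match_one_step_to_second_order(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(1.0, 8.0, self.grid.n_nodes)
        vals[-1] = COND.equilibrium_moisture
        d = 5e-10
        dt = stable_timestep(self.grid, d, 0.5)
        one = step_constant(MoistureField(self.grid, 0.0, vals.copy()), d, COND, dt)
        half = step_constant(MoistureField(self.grid, 0.0, vals.copy()), d, COND, dt / 2)
        half = step_constant(half, d, COND, dt / 2)
        # difference between the two is O(dt^2) in the update magnitude
        delta = np.abs(one.values - half.values).max()
        update = np.abs(one.values - vals).max()
        assert delta < 0.51 * update

    def test_symmetric_perturbation_amplitude_decays(self):
        grid = build_grid(2e-4, 8)
        base = np.full(grid.n_nodes, 4.0)
        bump = np.zeros(grid.n_nodes)
        bump[grid.n_layers // 2] = 1.0
        f = MoistureField(grid, 0.0, base + bump)
        d = 5e-10
        dt = stable_timestep(grid, d, 0.9)
        cond = DryingConditions(35.0, 60.0, 4.0)
        amp = [np.ptp(f.values[:-1])]
        for _ in range(20):
            f = step_constant(f, d, cond, dt)
            amp.append(np.ptp(f.values[:-1]))
        assert all(a2 <= a1 + 1e-15 for a1, a2 in zip(amp, amp[1:]))


class TestSimulate:
    grid = build_grid(2e-4, 4)
    params = DeffParams(D0=1e-6, Ea=3e4, a=0.2, b=0.05)

    def test_initial_snapshot_uniform_except_outer_node(self):
        h = simulate(8.44, self.params, COND, self.grid, 600.0, [0.0, 300.0, 600.0])
        np.testing.assert_allclose(h.fields[0][:-1], 8.44)
        assert h.fields[0][-1] == COND.equilibrium_moisture

    def test_long_run_reaches_equilibrium(self):
        t = np.linspace(0, 4e4, 9)[1:]
        h = simulate(8.44, self.params, COND, self.grid, 4e4, t)
        np.testing.assert_allclose(h.fields[-1], COND.equilibrium_moisture, atol=2e-2)

    def test_flat_history_when_starting_at_equilibrium(self):
        h = simulate(0.1, self.params, COND, self.grid, 600.0, [0.0, 300.0, 600.0])
        np.testing.assert_allclose(h.fields, COND.equilibrium_moisture, rtol=1e-14)

    def test_invalid_requests_rejected(self):
        with pytest.raises(ConfigError):
            simulate(8.44, self.params, COND, self.grid, -1.0, [0.0])
        with pytest.raises(ConfigError):
            simulate(8.44, self.params, COND, self.grid, 100.0, [0.0, 200.0])
        with pytest.raises(ConfigError):
            simulate(0.05, self.params, COND, self.grid, 100.0, [0.0, 50.0])

    def test_kernel_agrees_with_single_step_reference(self):
        """The compiled march must reproduce the numpy single-step path
        exactly (same stencil, same step-size policy)."""
        times = np.arange(1, 8) * 1200.0
        h = simulate(8.44, self.params, COND, self.grid, 8400.0, times)
        f = _uniform_field(self.grid, 8.44, m_e=COND.equilibrium_moisture)
        t, idx = 0.0, 0
        snaps = {}
        while t < 8400.0 and idx < times.size:
            d = np.max(
                effective_diffusivity(self.params, f.values, COND.temperature_k)
            )
            dt = min(stable_timestep(self.grid, float(d), 0.9), 8400.0 - t)
            prev_t, prev_v = t, f.values.copy()
            f = step_variable(f, self.params, COND, dt)
            t += dt
            while idx < times.size and times[idx] <= t:
                w = (times[idx] - prev_t) / (t - prev_t)
                snaps[idx] = (1 - w) * prev_v + w * f.values
                idx += 1
            mr = (average_moisture(f) - 0.1) / (8.44 - 0.1)
            if mr < 1e-3:
                break
        for i, v in snaps.items():
            np.testing.assert_allclose(h.fields[i], v, rtol=0, atol=0)

    def test_step_budget_guard(self):
        opts = SolverOptions(max_steps=3)
        with pytest.raises(NumericalError):
            simulate(
                8.44, None, COND, self.grid, 8400.0,
                np.arange(1, 8) * 1200.0, options=opts, constant_d=1e-11,
            )

    def test_grid_refinement_converges_at_first_order_or_better(self):
        d = 5e-10
        times = np.linspace(60.0, 240.0, 4)
        prev = None
        errs = []
        for z in (8, 16, 32):
            h = simulate(
                8.44, None, COND, build_grid(2e-4, z), 300.0, times, constant_d=d
            )
            avg = h.average()
            if prev is not None:
                errs.append(np.max(np.abs(avg - prev)))
            prev = avg
        assert errs[1] < 0.7 * errs[0]

    def test_boundary_variants_converge_together(self):
        """The printed coefficient-6 inner-node rule and the textbook
        ghost-node rule approach each other at first order in the spacing."""
        d = 5e-10
        times = np.linspace(30.0, 240.0, 6)
        diffs = []
        for z in (16, 64, 256):
            out = {}
            for scheme in ("paper", "ghost"):
                h = simulate(
                    8.44, None, COND, build_grid(2e-4, z), 300.0, times,
                    options=SolverOptions(boundary_scheme=scheme), constant_d=d,
                )
                out[scheme] = h.average()
            diffs.append(np.max(np.abs(out["paper"] - out["ghost"])) / (8.44 - 0.1))
        assert diffs[1] < 0.35 * diffs[0]
        assert diffs[2] < 0.35 * diffs[1]
        assert diffs[2] < 1e-3


class TestAnalyticSlabRatio:
    def test_series_sums_to_one_at_time_zero(self):
        assert analytic_slab_ratio(5e-10, 2e-4, 1e-12, 20000) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_late_time_first_term_dominates(self):
        d, length, t = 5e-10, 2e-4, 400.0
        full = analytic_slab_ratio(d, length, t, 50)
        first = (8 / np.pi**2) * np.exp(-np.pi**2 * d * t / (4 * length**2))
        assert full == pytest.approx(first, rel=1e-9)

    def test_frozen_oracle_value(self):
        # frozen from an arbitrary-precision summation of the series
        assert analytic_slab_ratio(5e-10, 2e-4, 40.0, 50) == pytest.approx(
            0.23604966925615119, rel=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            analytic_slab_ratio(5e-10, 2e-4, 40.0, 0)
        with pytest.raises(ConfigError):
            analytic_slab_ratio(-5e-10, 2e-4, 40.0, 10)


class TestSpatialSummaries:
    grid = build_grid(2e-4, 4)

    def test_average_of_uniform_field(self):
        f = _uniform_field(self.grid, 3.3)
        assert average_moisture(f) == pytest.approx(3.3, rel=1e-14)

    def test_average_of_linear_profile_is_midpoint(self):
        v = np.linspace(0.1, 8.44, self.grid.n_nodes)
        f = MoistureField(self.grid, 0.0, v)
        assert average_moisture(f) == pytest.approx((0.1 + 8.44) / 2, rel=1e-14)

    def test_average_matches_brute_force_trapezoid(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.0, 9.0, self.grid.n_nodes)
        f = MoistureField(self.grid, 0.0, v)
        dl = self.grid.spacing
        brute = sum(
            0.5 * (v[i] + v[i + 1]) * dl for i in range(self.grid.n_layers)
        ) / self.grid.thickness
        assert average_moisture(f) == pytest.approx(brute, rel=1e-13)

    def test_weighted_average_of_uniform_field_is_pointwise_value(self):
        p = DeffParams(D0=1e-6, Ea=3e4, a=0.2, b=0.05)
        f = _uniform_field(self.grid, 2.5)
        assert deff_avg(f, p, 308.15) == pytest.approx(
            effective_diffusivity(p, 2.5, 308.15), rel=1e-14
        )

    def test_weighted_average_constant_params_ignores_profile(self):
        p = DeffParams(D0=1e-6, Ea=3e4, a=0.0, b=0.0)
        v = np.linspace(0.5, 8.0, self.grid.n_nodes)
        f = MoistureField(self.grid, 0.0, v)
        from capsuledry import constant_diffusivity

        assert deff_avg(f, p, 308.15) == pytest.approx(
            constant_diffusivity(p, 308.15), rel=1e-14
        )

    def test_two_node_toy_weighted_mean(self):
        # additive linear law D = 1 + 2M: nodes {1, 3} give (3*1 + 7*3)/4 = 6
        grid = build_grid(1.0, 2)
        p = DeffParams(D0=1.0, Ea=0.0, a=2.0, b=0.0, form="additive")
        f = MoistureField(grid, 0.0, np.array([1.0, 3.0, 0.0]))
        expect = (3 * 1 + 7 * 3 + 1 * 0) / 4.0  # D(0)=1 carries zero weight
        assert deff_avg(f, p, 300.0) == pytest.approx(expect, rel=1e-14)

    def test_all_dry_field_raises(self):
        f = _uniform_field(self.grid, 0.0)
        p = DeffParams(D0=1e-9, Ea=0.0, a=0.0, b=0.0)
        with pytest.raises(NumericalError):
            deff_avg(f, p, 300.0)
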