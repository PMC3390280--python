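"""Circulation, colonization intensities, colony registries, higher orders."""

import numpy as np
import pytest

from conftest import event_mc_cascade

from metasim.cascade import (
    CirculationParams,
    GrowthVariant,
    build_colony_registry,
    circulation_step,
    colonies_above,
    first_order_intensity,
    full_cascade,
    higher_order_intensity,
    mass_parity_time,
    metastatic_mass,
)
from metasim.growth import (
    GenerationConfig,
    GompertzParams,
    fit_gdr_decrement,
    gdr_trajectory,
    gdr_log_asymptote,
    ms_trajectory,
)


class TestCirculationStep:
    def test_empty_compartment(self):
        res = circulation_step(0.0, 0.0, CirculationParams(), T=4.0)
        assert res.surviving_pool == res.surviving_new == res.colonizers == 0.0

    def test_pool_decay_closed_form(self):
        res = circulation_step(1.0, 0.0, CirculationParams(T_env=1.0), T=4.07)
        assert res.surviving_pool == pytest.approx(np.exp(-4.07), rel=1e-12)

    def test_uniform_entry_survival_closed_form(self):
        res = circulation_step(0.0, 1.0, CirculationParams(T_env=1.0), T=4.07)
        assert res.surviving_new == pytest.approx(
            (1.0 - np.exp(-4.07)) / 4.07, rel=1e-12
        )

    def test_against_per_cell_simulation(self):
        """Closed forms vs 200k simulated cells (survival, colonizers, mean time)."""
        rng = np.random.default_rng(42)
        T, T_env, c = 3.0, 1.3, 0.4
        n = 200_000
        # old pool cells
        life_old = rng.exponential(T_env, n)
        # uniform-entry cells
        entry = rng.random(n) * T
        death_new = entry + rng.exponential(T_env, n)
        res = circulation_step(1.0, 1.0, CirculationParams(T_env, c), T)
        surv_old = np.mean(life_old > T)
        surv_new = np.mean(death_new > T)
        assert res.surviving_pool == pytest.approx(surv_old, abs=3 * 0.5 / np.sqrt(n))
        assert res.surviving_new == pytest.approx(surv_new, abs=3 * 0.5 / np.sqrt(n))
        eliminated_times = np.concatenate(
            [life_old[life_old <= T], death_new[death_new <= T]]
        )
        assert res.colonizers == pytest.approx(
            c * len(eliminated_times) / n, rel=0.01
        )
        assert res.mean_colonization_time == pytest.approx(
            float(np.mean(eliminated_times)), rel=0.01
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            circulation_step(-1.0, 0.0, CirculationParams(), 1.0)


@pytest.fixture(scope="module")
def small_gdr():
    """Small, fast GDR instance with inflated rates for oracle comparisons."""
    p = GompertzParams(b=1e4, mu=0.05)
    eps = fit_gdr_decrement(p)
    cfg = GenerationConfig(
        engine="GDR", T_G0=3.0, d_i=2 / 3, m=5e-3, alpha_d=1.0, epsilon=eps
    )
    circ = CirculationParams(T_env=1.0, c_frac=0.2)
    traj = gdr_trajectory(p, cfg, horizon=120.0)
    return p, cfg, circ, traj


@pytest.fixture(scope="module")
def hepato_ms(hepato_params, hepato_T_G0, hepato_circ):
    cfg = GenerationConfig(
        engine="MS", T_G0=hepato_T_G0, m=2.554e-6, alpha_d=1.0
    )
    traj = ms_trajectory(hepato_params, cfg, horizon=2200.0)
    intensity = first_order_intensity(traj, hepato_circ)
    registry = build_colony_registry(
        intensity, GrowthVariant(), hepato_params, cfg, traj
    )
    return cfg, traj, intensity, registry


class TestFirstOrderIntensity:
    def test_conservation_all_cells_resolve(self, small_gdr):
        """Every circulating cell is eventually eliminated; colonizers are
        exactly c_frac of all disseminated cells once the pool has drained."""
        p, cfg, circ, traj = small_gdr
        intensity = first_order_intensity(traj, circ)
        assert intensity.total() == pytest.approx(
            circ.c_frac * intensity.total_disseminated, rel=1e-9
        )
        assert intensity.residual_pool <= 1e-10 * intensity.total_disseminated
        assert np.all(intensity.lambda_j >= 0)

    def test_grid_refinement_stability(self, hepato_params, hepato_circ, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        fine = first_order_intensity(traj, hepato_circ, grid_dt=0.5)
        reg_fine = build_colony_registry(
            fine, GrowthVariant(), hepato_params, cfg, traj
        )
        for t in (900.0, 1110.0):
            a = registry.visible_count(t, 4.6e7)
            b = reg_fine.visible_count(t, 4.6e7)
            assert b == pytest.approx(a, rel=0.01)

    def test_excision_stops_influx_but_pool_resolves(self, small_gdr):
        p, cfg, circ, traj = small_gdr
        t_exc = 60.0
        cut = first_order_intensity(traj, circ, excision_time=t_exc)
        full = first_order_intensity(traj, circ)
        # before excision identical
        j = int(t_exc) - 3
        np.testing.assert_allclose(cut.lambda_j[:j], full.lambda_j[:j], rtol=1e-9)
        # afterwards only the residual pool tail: negligible past a few lifetimes
        tail_start = int((t_exc + 12 * circ.T_env) / cut.dt)
        assert cut.lambda_j[tail_start:].sum() < 1e-6 * cut.total()
        assert cut.total() < full.total()

    def test_mean_times_lie_inside_bins(self, small_gdr):
        p, cfg, circ, traj = small_gdr
        intensity = first_order_intensity(traj, circ)
        edges = intensity.edges
        ok = intensity.lambda_j > 0
        assert np.all(intensity.mean_t_j[ok] >= edges[:-1][ok])
        assert np.all(intensity.mean_t_j[ok] <= edges[1:][ok])


class TestRegistryVariants:
    def test_primary_like_colony_mirrors_primary_curve(self, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        s = registry.seed_t[0]
        for age in (100.0, 300.0, 600.0):
            colony = registry.sizes_at(s + age)[0]
            assert colony == pytest.approx(float(traj.size_at(age)), rel=1e-6)

    def test_ms_inherited_TG_slows_by_stretch(self, hepato_params, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        inh = build_colony_registry(
            intensity, GrowthVariant("ms_inherited_TG"), hepato_params, cfg, traj
        )
        # same asymptotic size, time to any size scaled by the inherited stretch
        t_cross = registry.threshold_crossing_times(1e6)
        t_cross_inh = inh.threshold_crossing_times(1e6)
        stretch = inh._stretch
        np.testing.assert_allclose(
            t_cross_inh - inh.seed_t,
            (t_cross - registry.seed_t) * stretch,
            rtol=1e-9,
        )
        assert np.all(stretch[1:] >= stretch[0])

    def test_gdr_inherited_d_reduces_colony_asymptote(
        self, hepato_params, hepato_T_G0, hepato_circ
    ):
        """A colony founded at generation k starts from the decayed doubling
        fraction d_k; its asymptote matches the tail-series oracle and is
        smaller than b."""
        eps = fit_gdr_decrement(hepato_params)
        cfg = GenerationConfig(
            engine="GDR", T_G0=hepato_T_G0, m=1e-6, alpha_d=2 / 3, epsilon=eps
        )
        traj = gdr_trajectory(hepato_params, cfg, horizon=2200.0)
        intensity = first_order_intensity(traj, hepato_circ)
        reg = build_colony_registry(
            intensity, GrowthVariant("gdr_inherited_d"), hepato_params, cfg, traj
        )
        i = len(reg.seed_t) // 2
        k = int(reg.seed_gen[i])
        # independent series oracle for the tail asymptote
        e0 = (2 * cfg.d_i - 1) * (1 - eps) ** k
        tail = sum(np.log1p(e0 * (1 - eps) ** j) for j in range(200_000))
        colony_at_infinity = reg.sizes_at(reg.seed_t[i] + 1e7)[i]
        assert np.log(colony_at_infinity) == pytest.approx(tail, rel=1e-3)
        assert colony_at_infinity < hepato_params.b

    def test_variant_engine_mismatch_rejected(self, hepato_params, hepato_ms):
        cfg, traj, intensity, _ = hepato_ms
        with pytest.raises(ValueError):
            build_colony_registry(
                intensity, GrowthVariant("gdr_inherited_d"), hepato_params, cfg, traj
            )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            GrowthVariant("exponential")


class TestRegistryQueries:
    def test_colonies_above_one_cell_counts_everything(self, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        t_late = intensity.t_end
        assert colonies_above(registry, 1.0, t_late) == pytest.approx(
            intensity.total(), rel=1e-6
        )

    def test_no_colonies_before_first_seed(self, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        assert colonies_above(registry, 4.6e7, registry.seed_t[0] + 1.0) == 0.0

    def test_zero_dissemination_zero_mass(self, hepato_params, hepato_T_G0, hepato_circ):
        cfg = GenerationConfig(engine="MS", T_G0=hepato_T_G0, m=0.0)
        traj = ms_trajectory(hepato_params, cfg, horizon=2200.0)
        intensity = first_order_intensity(traj, hepato_circ)
        registry = build_colony_registry(
            intensity, GrowthVariant(), hepato_params, cfg, traj
        )
        assert metastatic_mass(registry, 2000.0) == 0.0
        assert mass_parity_time(registry, traj) is None

    def test_parity_time_decreases_with_m(
        self, hepato_params, hepato_T_G0, hepato_circ
    ):
        days = []
        for m in (1e-6, 4e-6, 1.6e-5):
            cfg = GenerationConfig(engine="MS", T_G0=hepato_T_G0, m=m, alpha_d=1.0)
            traj = ms_trajectory(hepato_params, cfg, horizon=2200.0)
            intensity = first_order_intensity(traj, hepato_circ)
            registry = build_colony_registry(
                intensity, GrowthVariant(), hepato_params, cfg, traj
            )
            days.append(mass_parity_time(registry, traj))
        assert days[0] > days[1] > days[2]

    def test_excision_cuts_late_first_order_mass_by_decades(
        self, hepato_params, hepato_circ, hepato_ms
    ):
        """Removing the primary at diagnosis starves the cascade: late
        first-order metastatic mass drops by roughly two orders of magnitude."""
        cfg, traj, intensity, registry = hepato_ms
        cut_int = first_order_intensity(traj, hepato_circ, excision_time=678.0)
        cut_reg = build_colony_registry(
            cut_int, GrowthVariant(), hepato_params, cfg, traj
        )
        t = 2100.0
        ratio = metastatic_mass(registry, t) / metastatic_mass(cut_reg, t)
        assert 10.0 < ratio < 1e4


class TestHigherOrders:
    def test_max_order_one_yields_nothing_beyond_first(self, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        from metasim.cascade import CirculationParams

        assert higher_order_intensity(registry, CirculationParams(), cfg, 1) == []
        with pytest.raises(ValueError):
            higher_order_intensity(registry, CirculationParams(), cfg, 0)

    def test_second_order_negligible_at_calibration_day(
        self, hepato_params, hepato_circ, hepato_ms
    ):
        """Second-order visible colonies are far below first order at day 1110."""
        cfg, traj, intensity, registry = hepato_ms
        second = higher_order_intensity(registry, hepato_circ, cfg, 2)[0]
        reg2 = build_colony_registry(
            second, GrowthVariant(), hepato_params, cfg, traj
        )
        assert reg2.visible_count(1110.0, 4.6e7) < 1e-2
        assert second.cumulative(1110.0) < 0.05 * intensity.cumulative(1110.0)

    def test_expected_cascade_matches_event_simulation(self, small_gdr):
        """Expected-value bookkeeping vs a per-cell event-driven Monte Carlo
        (inflated rates): per-order totals agree within 3 standard errors."""
        p, cfg, circ, traj = small_gdr
        horizon = 120.0
        intensities, _ = full_cascade(
            traj, circ, GrowthVariant(), grid_dt=0.5, max_order=2
        )
        expected = [i.cumulative(horizon) for i in intensities]
        counts = event_mc_cascade(cfg, circ, horizon, n_rep=400, seed=11, max_order=2)
        for k in range(2):
            mc_mean = counts[:, k].mean()
            mc_se = counts[:, k].std(ddof=1) / np.sqrt(len(counts))
            assert abs(expected[k] - mc_mean) < 3.0 * max(mc_se, 1e-9), (
                f"order {k+1}: expected {expected[k]:.3f}, MC {mc_mean:.3f} ± {mc_se:.3f}"
            )

    def test_order_totals_decrease_during_observation_window(self, hepato_ms):
        cfg, traj, intensity, registry = hepato_ms
        from metasim.cascade import CirculationParams

        circ = CirculationParams()
        intensities = higher_order_intensity(registry, circ, cfg, 3)
        totals = [intensity.cumulative(1310.0)] + [
            i.cumulative(1310.0) for i in intensities
        ]
        assert totals[0] > totals[1] > totals[2]
        assert all(np.all(i.lambda_j >= 0) for i in intensities)
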