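import numpy as np
import numpy.testing as npt
import pytest

from restoreplan.growth_cost import (
    CostSchedule,
    EconomyParams,
    MethodCost,
    agb_gain,
    agc_to_agb,
    compute_cost,
    cost_effectiveness,
    years_to_recovery,
    years_until_deficit_below,
)
from restoreplan.method_rules import METHOD_CODES, MethodMap
from restoreplan.scenarios import GrowthParams, REALISTIC

G = REALISTIC.growth  # p20=0.51, r1=7.28, r2=2.56


def simulate_gain(current, maximum, g, horizon, dt=1e-3):
    """Fine-step trajectory integration oracle."""
    agb = current
    t = 0.0
    while t < horizon and agb < maximum:
        rate = g.r1 if agb < g.p20 * maximum else g.r2
        agb = min(agb + rate * dt, maximum)
        t += dt
    return agb - current


def simulate_years(current, maximum, g, dt=0.05):
    agb, t = current, 0.0
    while agb < maximum:
        rate = g.r1 if agb < g.p20 * maximum else g.r2
        agb = min(agb + rate * dt, maximum)
        t += dt
    return t


class TestCarbonConversion:
    def test_stated_fraction_inverts_to_agb(self):
        assert agc_to_agb(45.6, 0.456) == pytest.approx(100.0)

    def test_zero(self):
        assert agc_to_agb(0.0) == 0.0

    def test_round_trip(self):
        from restoreplan.growth_cost import agb_to_agc

        agb = np.array([0.0, 10.0, 250.0])
        npt.assert_allclose(agc_to_agb(agb_to_agc(agb, 0.44), 0.44), agb)

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError):
            agc_to_agb(10.0, 0.0)


class TestAgbGain:
    def test_bare_pixel_five_year_gain(self):
        # heavily deficient pixel: 5 years at the fast phase rate
        assert agb_gain(0.0, 300.0, G, 5.0) == pytest.approx(5 * 7.28)

    def test_saturated_pixel_gains_nothing(self):
        for h in (0, 5, 100):
            assert agb_gain(120.0, 120.0, G, h) == 0.0

    def test_slow_phase_capped_by_deficit(self):
        # current above the phase-change point: slow rate, capped at deficit
        assert agb_gain(100.0, 120.0, G, 5.0) == pytest.approx(
            min(5 * 2.56, 20.0)
        )

    def test_matches_fine_step_simulation(self, rng):
        maximum = rng.uniform(50, 350, size=20)
        current = maximum * rng.uniform(0, 1, size=20)
        for h in (2.0, 10.0, 40.0):
            expected = [simulate_gain(c, m, G, h) for c, m in zip(current, maximum)]
            npt.assert_allclose(agb_gain(current, maximum, G, h), expected, atol=0.05)

    def test_gain_monotone_and_saturating_in_horizon(self, rng):
        cur, mx = 20.0, 180.0
        horizons = np.linspace(0, 120, 60)
        gains = agb_gain(cur, mx, G, horizons)
        assert np.all(np.diff(gains) >= -1e-12)
        assert gains[-1] == pytest.approx(mx - cur)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            agb_gain(0.0, 100.0, G, -1.0)


class TestYearsToRecovery:
    def test_single_phase_closed_form_from_knee(self):
        mx = 200.0
        cur = G.p20 * mx
        assert years_to_recovery(cur, mx, G) == pytest.approx((mx - cur) / G.r2)

    def test_degenerate_single_phase_config(self):
        g = GrowthParams(p20=1.0, r1=7.28, r2=2.56)
        assert years_to_recovery(0.0, 145.6, g) == pytest.approx(20.0)

    def test_recovered_pixel_is_zero(self):
        assert years_to_recovery(100.0, 100.0, G) == 0.0

    def test_matches_stepping_within_one_year(self, rng):
        maximum = rng.uniform(50, 350, size=15)
        current = maximum * rng.uniform(0, 0.99, size=15)
        analytic = years_to_recovery(current, maximum, G)
        stepped = [simulate_years(c, m, G) for c, m in zip(current, maximum)]
        npt.assert_allclose(analytic, stepped, atol=1.0)

    def test_monotone_decreasing_in_current(self):
        mx = 250.0
        cur = np.linspace(0, 249, 50)
        t = years_to_recovery(cur, mx, G)
        assert np.all(np.diff(t) < 0)

    def test_years_until_threshold_consistent_with_gain(self):
        cur, mx, thr = 30.0, 200.0, 40.0  # reach <40% deficit = 120 Mg
        t = years_until_deficit_below(cur, mx, G, thr)
        reached = cur + agb_gain(cur, mx, G, t)
        assert 100.0 * (mx - reached) / mx == pytest.approx(thr, abs=1e-9)


def _uniform_schedule(treatment=100.0, admin=0.0, **kw) -> CostSchedule:
    mc = MethodCost(
        treatment_cost=treatment, treatments_per_year=1.0, active_years=1000.0, **kw
    )
    return CostSchedule(
        methods={name: mc for name in METHOD_CODES if name != "none"},
        community_engagement_per_ha_yr=0.0,
        admin_overhead=admin,
    )


def _method_map(codes) -> MethodMap:
    return MethodMap(method=np.asarray(codes, dtype=np.int16), scenario="test")


class TestComputeCost:
    def _run(self, schedule, horizon, inflation=0.0, pa=False):
        mm = _method_map([[METHOD_CODES["passive"]]])
        pa_mask = np.array([[pa]])
        far = np.array([[1e9]])
        return compute_cost(
            mm, pa_mask, far, schedule, EconomyParams(inflation=inflation), horizon
        )[0, 0]

    def test_flat_annual_schedule(self):
        sched = _uniform_schedule(treatment=100.0)
        for h in (1, 5, 30):
            assert self._run(sched, h) == pytest.approx(100.0)

    def test_two_year_inflation_arithmetic(self):
        sched = _uniform_schedule(treatment=100.0)
        assert self._run(sched, 2, inflation=0.022) == pytest.approx((100 + 102.2) / 2)

    def test_land_procurement_waived_inside_protected_areas(self):
        sched = _uniform_schedule(treatment=0.0, land_procurement=500.0)
        outside = self._run(sched, 5, pa=False)
        inside = self._run(sched, 5, pa=True)
        assert outside == pytest.approx(100.0)  # 500 amortized over 5 years
        assert inside == 0.0

    def test_linear_in_unit_prices(self, rng):
        mm = _method_map(
            rng.choice([1, 2, 6], size=(8, 8)).astype(np.int16)
        )
        pa = rng.random((8, 8)) < 0.3
        sdist = rng.uniform(0, 5000, size=(8, 8))
        econ = EconomyParams()
        base = CostSchedule(
            methods={
                n: MethodCost(
                    land_procurement=500,
                    treatment_cost=200,
                    treatments_per_year=2,
                    active_years=5,
                    staff_cost_per_year=10000,
                    oversight_area=100,
                    nursery_cost=5000,
                    nursery_service_area=50,
                    transport_cost_per_visit=100,
                    visits_per_year=3,
                    transport_service_area=40,
                )
                for n in METHOD_CODES
                if n != "none"
            },
            community_engagement_per_ha_yr=50,
            admin_overhead=0.15,
        )
        doubled = CostSchedule(
            methods={
                n: MethodCost(
                    **{
                        k: (v * 2 if "cost" in k or k in ("land_procurement",) else v)
                        for k, v in base.methods[n].__dict__.items()
                    }
                )
                for n in base.methods
            },
            community_engagement_per_ha_yr=100,
            admin_overhead=0.15,
        )
        c1 = compute_cost(mm, pa, sdist, base, econ, 5.0)
        c2 = compute_cost(mm, pa, sdist, doubled, econ, 5.0)
        npt.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_patch_economies_of_scale(self):
        # a 3x3 contiguous block shares staff; an isolated pixel pays full share
        method = np.zeros((6, 6), dtype=np.int16)
        method[:3, :3] = METHOD_CODES["passive"]
        method[5, 5] = METHOD_CODES["passive"]
        sched = _uniform_schedule(
            treatment=0.0, staff_cost_per_year=900.0, oversight_area=100.0
        )
        cost = compute_cost(
            _method_map(method),
            np.zeros((6, 6), bool),
            np.full((6, 6), 1e9),
            sched,
            EconomyParams(inflation=0.0),
            1.0,
        )
        assert cost[0, 0] == pytest.approx(100.0)  # 900 / 9 ha patch
        assert cost[5, 5] == pytest.approx(900.0)

    def test_missing_method_entry_rejected(self):
        sched = CostSchedule(methods={"passive": MethodCost()})
        mm = _method_map([[METHOD_CODES["framework_planting"]]])
        with pytest.raises(KeyError):
            compute_cost(
                mm, np.array([[False]]), np.array([[1e9]]), sched, EconomyParams(), 5.0
            )


class TestCostEffectiveness:
    def test_arithmetic(self):
        assert cost_effectiveness(10.0, 500.0) == pytest.approx(2.0)

    def test_zero_gain(self):
        assert cost_effectiveness(0.0, 500.0) == 0.0

    def test_homogeneity(self):
        assert cost_effectiveness(10.0, 1000.0) == pytest.approx(
            cost_effectiveness(10.0, 500.0) / 2
        )

    def test_nonpositive_cost_undefined(self):
        with pytest.warns(UserWarning):
            out = cost_effectiveness(np.array([5.0]), np.array([0.0]))
        assert np.isnan(out[0])


class TestGrowthParamsValidation:
    def test_rate_order_enforced(self):
        with pytest.raises(ValueError):
            GrowthParams(r1=2.0, r2=3.0)

    def test_p20_bounds(self):
        with pytest.raises(ValueError):
            GrowthParams(p20=0.0)
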