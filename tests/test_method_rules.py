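import numpy as np
import numpy.testing as npt
import pytest

from restoreplan.grids import LANDCOVER_CODES
from restoreplan.method_rules import (
    METHOD_CODES,
    assign_methods,
    compute_deficit,
    distance_to,
    intact_mask,
)
from restoreplan.scenarios import (
    DEFAULT_SCENARIOS,
    OPTIMISTIC,
    PESSIMISTIC,
    REALISTIC,
    ScenarioParams,
)

F = LANDCOVER_CODES["moist_forest"]
S = LANDCOVER_CODES["savanna"]
A = LANDCOVER_CODES["agro_mosaic"]
FP = LANDCOVER_CODES["floodplain"]


def oracle_method(pct, lc, elev, d_intact, d_dist, sc: ScenarioParams) -> int:
    """Independent per-pixel re-statement of the decision framework, one
    predicate per rule row, evaluated in severity order."""
    if not np.isfinite(pct) or pct <= 0:
        return METHOD_CODES["none"]
    if pct >= sc.soil_nurse_at_or_above:
        return METHOD_CODES["soil_improvement_nurse_planting"]
    if (
        sc.planting_lower <= pct < sc.planting_upper
        and d_intact >= sc.planting_dist_min_from_intact
    ):
        return METHOD_CODES["framework_planting"]
    passive_thr = sc.forest_passive_below if lc == F else sc.savanna_passive_below
    if pct >= passive_thr:
        if lc == F:
            if (
                sc.lantana_dist_max is not None
                and elev < sc.lantana_elev_below
                and d_dist <= sc.lantana_dist_max
            ):
                return METHOD_CODES["lantana_removal"]
            if elev < sc.vine_cut_elev_below:
                return METHOD_CODES["vine_cutting"]
            return METHOD_CODES["herb_shrub_cutting"]
        return METHOD_CODES["firebreak_and_grass_cutting"]
    return METHOD_CODES["passive"]


def _single_pixel(pct, lc, elev, d_intact, d_dist, sc):
    deficit = compute_deficit(
        np.array([[100.0 - pct]]), np.array([[100.0]])
    )
    mm = assign_methods(
        deficit,
        np.array([[lc]]),
        np.array([[float(elev)]]),
        np.array([[float(d_intact)]]),
        np.array([[float(d_dist)]]),
        sc,
    )
    return int(mm.method[0, 0])


class TestComputeDeficit:
    def test_identity_no_potential(self):
        d = compute_deficit(np.full((2, 2), 80.0), np.full((2, 2), 80.0))
        npt.assert_allclose(d.absolute, 0.0)
        npt.assert_allclose(d.percent, 0.0)
        assert not d.potential_mask.any()

    def test_half_deficit(self):
        d = compute_deficit(np.array([[50.0]]), np.array([[100.0]]))
        assert d.absolute[0, 0] == 50.0
        assert d.percent[0, 0] == 50.0
        assert d.potential_mask[0, 0]

    def test_negative_deficit_excluded(self):
        d = compute_deficit(np.array([[120.0]]), np.array([[100.0]]))
        assert not d.potential_mask[0, 0]

    def test_zero_maximum_is_nodata(self):
        d = compute_deficit(np.array([[0.0]]), np.array([[0.0]]))
        assert np.isnan(d.percent[0, 0])
        assert not d.potential_mask[0, 0]

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            compute_deficit(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDistanceTo:
    def test_rook_and_diagonal_steps(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        d = distance_to(mask, cell_size=100.0)
        assert d[1, 1] == 0.0
        assert d[0, 1] == pytest.approx(100.0)
        assert d[0, 0] == pytest.approx(141.4213562)

    def test_matches_brute_force(self, rng):
        mask = rng.random((50, 50)) < 0.02
        mask[7, 31] = True  # guarantee nonempty
        d = distance_to(mask, cell_size=25.0)
        rr, cc = np.nonzero(mask)
        ii, jj = np.mgrid[0:50, 0:50]
        expected = np.sqrt(
            (ii[..., None] - rr) ** 2 + (jj[..., None] - cc) ** 2
        ).min(axis=-1) * 25.0
        npt.assert_allclose(d, expected, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            distance_to(np.zeros((4, 4), dtype=bool), 100.0)


class TestIntactMask:
    def test_forest_below_realistic_threshold_is_intact(self):
        d = compute_deficit(np.array([[70.0]]), np.array([[100.0]]))  # 30%
        assert intact_mask(d, np.array([[F]]), REALISTIC)[0, 0]

    def test_savanna_above_realistic_threshold_not_intact(self):
        d = compute_deficit(np.array([[55.0]]), np.array([[100.0]]))  # 45%
        assert not intact_mask(d, np.array([[S]]), REALISTIC)[0, 0]

    def test_undegraded_landscape_all_intact(self):
        cur = np.full((4, 4), 90.0)
        d = compute_deficit(cur, cur)
        lc = np.full((4, 4), S)
        assert intact_mask(d, lc, REALISTIC).all()

    def test_unknown_landcover_rejected(self):
        d = compute_deficit(np.zeros((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError):
            intact_mask(d, np.array([[99]]), REALISTIC)


class TestAssignMethodsExamples:
    def test_midslope_forest_gets_vine_cutting(self):
        code = _single_pixel(55, F, 900, 1000, 5000, REALISTIC)
        assert code == METHOD_CODES["vine_cutting"]

    def test_severely_degraded_savanna_gets_soil_nurse_planting(self):
        code = _single_pixel(97, S, 500, 1000, 5000, REALISTIC)
        assert code == METHOD_CODES["soil_improvement_nurse_planting"]

    def test_planting_suppressed_near_intact_forest(self):
        # deficit in the planting band but 50 m from intact habitat: seed
        # dispersal reaches it, so ANR applies; at 1200 m it is herb/shrub
        code = _single_pixel(70, F, 1200, 50, 5000, REALISTIC)
        assert code == METHOD_CODES["herb_shrub_cutting"]

    def test_no_potential_maps_to_none(self):
        code = _single_pixel(0, F, 500, 1000, 1000, REALISTIC)
        assert code == METHOD_CODES["none"]

    def test_lantana_rule_disabled_in_optimistic_scenario(self):
        # same pixel: low forest near disturbance
        assert _single_pixel(45, F, 800, 50, 50, PESSIMISTIC) == METHOD_CODES[
            "lantana_removal"
        ]
        assert _single_pixel(85, F, 800, 50, 50, OPTIMISTIC) == METHOD_CODES[
            "vine_cutting"
        ]


def _random_layers(rng, n):
    pct = rng.uniform(-10, 110, size=n)
    pct[rng.random(n) < 0.05] = 0.0
    lc = rng.choice([F, S, A, FP], size=n)
    elev = rng.uniform(100, 2500, size=n)
    d_intact = rng.uniform(0, 1000, size=n)
    d_dist = rng.uniform(0, 1000, size=n)
    # snap a share of values onto rule boundaries to probe edge handling
    for arr, vals in (
        (pct, [30, 40, 50, 65, 80, 90, 95, 100]),
        (elev, [1000, 1400]),
        (d_intact, [100, 200, 300]),
        (d_dist, [100, 200]),
    ):
        hit = rng.random(n) < 0.2
        arr[hit] = rng.choice(vals, size=hit.sum())
    return pct, lc, elev, d_intact, d_dist


class TestRuleEngineProperties:
    @pytest.mark.parametrize("scenario", list(DEFAULT_SCENARIOS))
    def test_matches_predicate_oracle(self, rng, scenario):
        sc = DEFAULT_SCENARIOS[scenario]
        n = 2000
        pct, lc, elev, d_intact, d_dist = _random_layers(rng, n)
        maximum = np.full(n, 100.0)
        deficit = compute_deficit((100.0 - pct).reshape(1, -1), maximum.reshape(1, -1))
        mm = assign_methods(
            deficit,
            lc.reshape(1, -1),
            elev.reshape(1, -1),
            d_intact.reshape(1, -1),
            d_dist.reshape(1, -1),
            sc,
        )
        expected = np.array(
            [
                oracle_method(deficit.percent[0, i], lc[i], elev[i], d_intact[i], d_dist[i], sc)
                for i in range(n)
            ]
        )
        npt.assert_array_equal(mm.method[0], expected)

    def test_classes_partition_pixels(self, rng):
        pct, lc, elev, d_intact, d_dist = _random_layers(rng, 1000)
        deficit = compute_deficit((100.0 - pct).reshape(1, -1), np.full((1, 1000), 100.0))
        mm = assign_methods(
            deficit, lc.reshape(1, -1), elev.reshape(1, -1),
            d_intact.reshape(1, -1), d_dist.reshape(1, -1), REALISTIC,
        )
        counts = sum(mm.class_mask(c).sum() for c in ("none", "passive", "anr", "planting"))
        assert counts == 1000
        npt.assert_array_equal(mm.method == 0, ~deficit.potential_mask)

    def test_pessimistic_intervention_superset_of_realistic(self, rng):
        pct, lc, elev, d_intact, d_dist = _random_layers(rng, 1500)
        deficit = compute_deficit((100.0 - pct).reshape(1, -1), np.full((1, 1500), 100.0))
        masks = {}
        for sc in (PESSIMISTIC, REALISTIC, OPTIMISTIC):
            mm = assign_methods(
                deficit, lc.reshape(1, -1), elev.reshape(1, -1),
                d_intact.reshape(1, -1), d_dist.reshape(1, -1), sc,
            )
            masks[sc.name] = mm.class_mask("anr") | mm.class_mask("planting")
        assert masks["pessimistic"].sum() >= masks["realistic"].sum() >= masks["optimistic"].sum()
        # set inclusion, not just counts
        assert (masks["realistic"] & ~masks["pessimistic"]).sum() == 0


class TestScenarioValidation:
    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            ScenarioParams(
                name="bad",
                forest_passive_below=70.0,
                savanna_passive_below=40.0,
                planting_lower=65.0,
                planting_upper=95.0,
                soil_nurse_at_or_above=95.0,
                planting_dist_min_from_intact=200.0,
            )

    def test_table_orderings_hold_across_bundles(self):
        p, r, o = PESSIMISTIC, REALISTIC, OPTIMISTIC
        assert p.forest_passive_below <= r.forest_passive_below <= o.forest_passive_below
        assert p.savanna_passive_below <= r.savanna_passive_below <= o.savanna_passive_below
        assert p.planting_lower <= r.planting_lower <= o.planting_lower
        assert p.soil_nurse_at_or_above <= r.soil_nurse_at_or_above <= o.soil_nurse_at_or_above
        assert p.planting_dist_min_from_intact <= r.planting_dist_min_from_intact
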