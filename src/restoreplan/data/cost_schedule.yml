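# Default restoration cost schedule (USD).
#
# Structure mirrors field budgeting practice: per-treatment costs scale with
# treatments per year and years of active management; land procurement is a
# one-off waived inside protected areas; nurseries, staff and transport are
# shared units whose per-hectare share scales with the contiguous restored
# patch up to a service cap (economies of scale); community engagement
# applies near settlements outside protected areas; administration is an
# overhead fraction of the subtotal.  Magnitudes are illustrative defaults
# for an East-African context — analyses should substitute project budgets.
currency: USD
community_engagement_per_ha_yr: 50
engagement_distance_m: 2000
admin_overhead: 0.15
methods:
  passive:
    land_procurement: 500
    treatment_cost: 0
    treatments_per_year: 0
    active_years: 0
    staff_cost_per_year: 5000        # monitoring only
    oversight_area: 5000
    transport_cost_per_visit: 100
    visits_per_year: 1
    transport_service_area: 500
  vine_cutting: &anr
    land_procurement: 500
    treatment_cost: 400
    treatments_per_year: 2
    active_years: 5                  # fallback; pipeline derives ANR years dynamically
    staff_cost_per_year: 30000
    oversight_area: 2000
    transport_cost_per_visit: 150
    visits_per_year: 4
    transport_service_area: 200
  herb_shrub_cutting: *anr
  lantana_removal:
    land_procurement: 500
    treatment_cost: 500              # hand removal of invasives is labour-heavier
    treatments_per_year: 2
    active_years: 5
    staff_cost_per_year: 30000
    oversight_area: 2000
    transport_cost_per_visit: 150
    visits_per_year: 4
    transport_service_area: 200
  firebreak_and_grass_cutting:       # joint bundle: firebreak + grass cutting summed
    land_procurement: 500
    treatment_cost: 600
    treatments_per_year: 2
    active_years: 5
    staff_cost_per_year: 30000
    oversight_area: 2000
    transport_cost_per_visit: 150
    visits_per_year: 4
    transport_service_area: 200
  framework_planting:
    land_procurement: 500
    treatment_cost: 1500             # raise, plant, tend seedlings
    treatments_per_year: 2
    active_years: 5                  # fixed tending period
    nursery_cost: 30000
    nursery_service_area: 500
    staff_cost_per_year: 40000
    oversight_area: 1000
    transport_cost_per_visit: 200
    visits_per_year: 8
    transport_service_area: 100
  soil_improvement_nurse_planting:
    land_procurement: 500
    treatment_cost: 2000             # soil works + nurse species, then natives
    treatments_per_year: 2
    active_years: 6
    nursery_cost: 30000
    nursery_service_area: 500
    staff_cost_per_year: 40000
    oversight_area: 1000
    transport_cost_per_visit: 200
    visits_per_year: 8
    transport_service_area: 100
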