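"""Scenario parameter bundles: decision thresholds and growth-model variants.

Three named scenarios — pessimistic, realistic, optimistic — bundle every
tunable of the method-assignment framework (percent-AGB-deficit thresholds,
elevation limits, distance rules) together with the matching biomass-growth
parameter variant.  The pessimistic bundle assumes intervention is needed
at lower degradation and growth is slow; the optimistic bundle the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional


@dataclass(frozen=True)
class GrowthParams:
    """Piecewise biomass-accumulation parameters.

    carbon_fraction
        AGC per unit AGB (0.456 +/- 0.02).
    p20
        Proportion of maximum AGB reached after 20 years of recovery
        (0.51; range 0.32-0.63); p20 x maximum is the phase-change point
        of the trajectory.
    r1, r2
        Mean annual AGB increment (Mg ha-1 yr-1) below (7.28; 7.02-7.58)
        and above (2.56; 1.54-4.11) the phase-change point.
    """

    carbon_fraction: float = 0.456
    p20: float = 0.51
    r1: float = 7.28
    r2: float = 2.56

    def __post_init__(self) -> None:
        if not 0.0 < self.p20 <= 1.0:
            raise ValueError("p20 must be in (0, 1]")
        if not self.r1 > self.r2 > 0:
            raise ValueError("require r1 > r2 > 0")
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioParams:
    """One scenario's full threshold set (percent AGB deficit unless noted).

    ``lantana_dist_max`` is the maximum distance (m) from disturbed pixels
    (roads or agro-mosaic) at which invasive Lantana removal applies; None
    disables the rule (the optimistic bundle).
    """

    name: str
    forest_passive_below: float  # forest regenerates passively below this % deficit
    savanna_passive_below: float  # savanna/agro-mosaic/floodplain analogue
    planting_lower: float
    planting_upper: float
    soil_nurse_at_or_above: float
    planting_dist_min_from_intact: float  # metres
    vine_cut_elev_below: float = 1000.0  # metres
    lantana_elev_below: float = 1400.0  # metres
    lantana_dist_max: Optional[float] = 100.0  # metres; None = rule disabled
    growth: GrowthParams = GrowthParams()

    def __post_init__(self) -> None:
        if not self.planting_lower < self.planting_upper <= 100.0:
            raise ValueError("require planting_lower < planting_upper <= 100")
        if self.forest_passive_below > self.planting_lower:
            raise ValueError("forest passive threshold must not exceed planting_lower")
        if self.savanna_passive_below > self.planting_lower:
            raise ValueError("savanna passive threshold must not exceed planting_lower")


PESSIMISTIC = ScenarioParams(
    name="pessimistic",
    forest_passive_below=40.0,
    savanna_passive_below=30.0,
    planting_lower=50.0,
    planting_upper=90.0,
    soil_nurse_at_or_above=90.0,
    planting_dist_min_from_intact=100.0,
    lantana_dist_max=200.0,
    growth=GrowthParams(carbon_fraction=0.476, p20=0.32, r1=7.02, r2=1.54),
)

REALISTIC = ScenarioParams(
    name="realistic",
    forest_passive_below=50.0,
    savanna_passive_below=40.0,
    planting_lower=65.0,
    planting_upper=95.0,
    soil_nurse_at_or_above=95.0,
    planting_dist_min_from_intact=200.0,
    lantana_dist_max=100.0,
    growth=GrowthParams(),
)

OPTIMISTIC = ScenarioParams(
    name="optimistic",
    forest_passive_below=80.0,
    savanna_passive_below=50.0,
    planting_lower=80.0,
    planting_upper=100.0,
    soil_nurse_at_or_above=100.0,
    planting_dist_min_from_intact=300.0,
    lantana_dist_max=None,
    growth=GrowthParams(carbon_fraction=0.436, p20=0.63, r1=7.58, r2=4.11),
)

DEFAULT_SCENARIOS: Dict[str, ScenarioParams] = {
    s.name: s for s in (PESSIMISTIC, REALISTIC, OPTIMISTIC)
}


def scenario_to_dict(s: ScenarioParams) -> dict:
    d = {k: v for k, v in s.__dict__.items() if k != "growth"}
    d["growth"] = dict(s.growth.__dict__)
    return d


def scenario_from_dict(d: dict) -> ScenarioParams:
    d = dict(d)
    growth = d.pop("growth", None)
    g = GrowthParams(**growth) if growth else GrowthParams()
    return ScenarioParams(growth=g, **d)
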