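"""Scenario-ensemble execution, priority mapping and summary reporting.

The ensemble runs the deficit → method-assignment → growth/cost →
cost-effectiveness chain for each of the three scenarios and both
investment horizons (5 years, and per-pixel time to full AGB recovery),
then intersects per-layer top-quartile cost-effectiveness masks —
"consistently cost-effective" pixels — excluding climatically uncertain
areas, both overall (priority 1) and outside protected areas (priority 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .grids import GridSpec, LANDCOVER_NAMES, LandscapeStack, aggregate_block
from .growth_cost import (
    CEResult,
    CostSchedule,
    EconomyParams,
    agb_gain,
    compute_cost,
    cost_effectiveness,
    years_to_recovery,
    years_until_deficit_below,
)
from .method_rules import (
    METHOD_CODES,
    METHOD_NAMES,
    SILVICULTURE_CODES,
    MethodMap,
    assign_methods,
    compute_deficit,
    distance_to,
    intact_mask,
    passive_threshold_layer,
)
from .scenarios import DEFAULT_SCENARIOS, ScenarioParams

HORIZON_5Y = "5y"
HORIZON_FULL = "full"


@dataclass
class HectareLayers:
    """Analysis-scale (1 ha) layers aggregated from a fine stack."""

    grid: GridSpec
    current_agb: np.ndarray
    max_agb: np.ndarray
    landcover: np.ndarray
    elevation: np.ndarray
    pa_mask: np.ndarray
    road_mask: np.ndarray
    settlement_mask: np.ndarray


def to_hectare(
    stack: LandscapeStack,
    current_agb: Optional[np.ndarray] = None,
    max_agb: Optional[np.ndarray] = None,
) -> HectareLayers:
    """Aggregate a fine stack to the hectare grid.

    AGB densities and elevation average; landcover takes the block mode;
    masks are True where any fine cell is True.  ``current_agb`` /
    ``max_agb`` default to the stack's truth layers, so modelled rasters
    can be substituted when running the fitted pipeline.
    """
    f = stack.grid.aggregation_factor
    cur = stack["current_agb_true"] if current_agb is None else current_agb
    mx = stack["max_agb_true"] if max_agb is None else max_agb
    return HectareLayers(
        grid=stack.grid.hectare_grid(),
        current_agb=aggregate_block(cur, f, "mean"),
        max_agb=aggregate_block(mx, f, "mean"),
        landcover=aggregate_block(stack["landcover"], f, "mode"),
        elevation=aggregate_block(stack["elevation"], f, "mean"),
        pa_mask=aggregate_block(stack["pa_mask"], f, "mean") >= 0.5,
        road_mask=aggregate_block(stack["road_mask"], f, "any"),
        settlement_mask=aggregate_block(stack["settlement_mask"], f, "any"),
    )


@dataclass
class EnsembleResult:
    """Six CE layers (3 scenarios x 2 horizons) plus shared masks."""

    layers: Dict[Tuple[str, str], CEResult]
    potential_mask: np.ndarray
    uncertainty_mask: np.ndarray
    pa_mask: np.ndarray
    landcover: np.ndarray
    recovery_years: np.ndarray  # realistic-scenario years to full recovery

    def __post_init__(self) -> None:
        shapes = {l.cost_effectiveness.shape for l in self.layers.values()}
        shapes |= {self.uncertainty_mask.shape, self.pa_mask.shape}
        if len(shapes) != 1:
            raise ValueError("ensemble layers are misaligned")

    def method_map(self, scenario: str = "realistic") -> MethodMap:
        return self.layers[(scenario, HORIZON_5Y)].method_map


def run_scenario(
    hl: HectareLayers,
    scenario: ScenarioParams,
    schedule: CostSchedule,
    econ: EconomyParams,
    horizon_5y: float = 5.0,
) -> Dict[str, CEResult]:
    """Deficit → methods → growth/cost → CE for one scenario, both horizons."""
    from .grids import LANDCOVER_CODES
    from .method_rules import METHOD_TO_CLASS

    deficit = compute_deficit(hl.current_agb, hl.max_agb)
    cell = hl.grid.cell_size

    intact = intact_mask(deficit, hl.landcover, scenario)
    dist_intact = (
        distance_to(intact, cell)
        if intact.any()
        else np.full(hl.grid.shape, np.inf)
    )
    disturbed = hl.road_mask | (hl.landcover == LANDCOVER_CODES["agro_mosaic"])
    dist_disturbed = (
        distance_to(disturbed, cell)
        if disturbed.any()
        else np.full(hl.grid.shape, np.inf)
    )
    settlement_dist = (
        distance_to(hl.settlement_mask, cell)
        if hl.settlement_mask.any()
        else np.full(hl.grid.shape, np.inf)
    )

    methods = assign_methods(
        deficit, hl.landcover, hl.elevation, dist_intact, dist_disturbed, scenario
    )
    g = scenario.growth
    pot = deficit.potential_mask

    # active management: ANR runs until the trajectory crosses the ANR onset
    # threshold; planting and passive use their schedule defaults
    thr = passive_threshold_layer(hl.landcover, scenario)
    anr_years = years_until_deficit_below(hl.current_agb, hl.max_agb, g, thr)
    active = np.full(hl.grid.shape, np.nan)
    for code in np.unique(methods.method):
        name = METHOD_NAMES[int(code)]
        if name == "none":
            continue
        sel = methods.method == code
        if METHOD_TO_CLASS[int(code)] == SILVICULTURE_CODES["anr"]:
            active[sel] = np.ceil(anr_years[sel])
        else:
            active[sel] = schedule.methods[name].active_years

    recovery = np.where(pot, years_to_recovery(hl.current_agb, hl.max_agb, g), 0.0)
    horizon_full = np.maximum(recovery, 1.0)

    results: Dict[str, CEResult] = {}
    for label, horizon in ((HORIZON_5Y, horizon_5y), (HORIZON_FULL, horizon_full)):
        gain = np.where(pot, agb_gain(hl.current_agb, hl.max_agb, g, horizon), np.nan)
        cost = compute_cost(
            methods,
            hl.pa_mask,
            settlement_dist,
            schedule,
            econ,
            horizon,
            active_years=active,
            cell_area_ha=hl.grid.cell_area_ha,
        )
        ce = cost_effectiveness(gain, cost)
        results[label] = CEResult(
            scenario=scenario.name,
            horizon=label,
            agb_gain=gain,
            cost_usd=cost,
            cost_effectiveness=ce,
            method_map=methods,
        )
    return results


def run_ensemble(
    hl: HectareLayers,
    schedule: CostSchedule,
    econ: EconomyParams = EconomyParams(),
    scenarios: Mapping[str, ScenarioParams] = None,
    uncertainty_mask: Optional[np.ndarray] = None,
) -> EnsembleResult:
    """Run all scenario x horizon combinations on hectare layers."""
    scenarios = dict(scenarios or DEFAULT_SCENARIOS)
    layers: Dict[Tuple[str, str], CEResult] = {}
    recovery = None
    for name, sc in scenarios.items():
        try:
            res = run_scenario(hl, sc, schedule, econ)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"ensemble stage failed for scenario {name!r}") from exc
        for label, ce in res.items():
            layers[(name, label)] = ce
        if name == "realistic":
            recovery = np.where(
                compute_deficit(hl.current_agb, hl.max_agb).potential_mask,
                years_to_recovery(hl.current_agb, hl.max_agb, sc.growth),
                np.nan,
            )
    deficit = compute_deficit(hl.current_agb, hl.max_agb)
    unc = (
        np.zeros(hl.grid.shape, dtype=bool)
        if uncertainty_mask is None
        else np.asarray(uncertainty_mask, dtype=bool)
    )
    if recovery is None:
        any_sc = next(iter(scenarios.values()))
        recovery = np.where(
            deficit.potential_mask,
            years_to_recovery(hl.current_agb, hl.max_agb, any_sc.growth),
            np.nan,
        )
    return EnsembleResult(
        layers=layers,
        potential_mask=deficit.potential_mask,
        uncertainty_mask=unc,
        pa_mask=hl.pa_mask,
        landcover=hl.landcover,
        recovery_years=recovery,
    )


@dataclass
class PriorityMap:
    """Consistently top-quantile pixels overall and outside protected areas."""

    priority1: np.ndarray
    priority2: np.ndarray
    quantile: float


def _top_mask(ce: np.ndarray, candidates: np.ndarray, q: float) -> np.ndarray:
    vals = ce[candidates & np.isfinite(ce)]
    if vals.size == 0:
        return np.zeros(ce.shape, dtype=bool)
    thr = np.quantile(vals, 1.0 - q)
    with np.errstate(invalid="ignore"):
        return candidates & np.isfinite(ce) & (ce >= thr)


def top_quantile_mask(ensemble: EnsembleResult, q: float = 0.25) -> PriorityMap:
    """Intersect per-layer top-``q`` cost-effectiveness masks.

    Per layer the threshold is the (1-q) linear-interpolation quantile of
    CE over candidate pixels (restoration potential, finite CE); ties at
    the threshold are included.  ``priority1`` intersects all six layers
    and removes climatically uncertain pixels; ``priority2`` repeats the
    construction with protected-area pixels removed from every candidate
    set.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    pot = ensemble.potential_mask

    p1 = np.ones(pot.shape, dtype=bool)
    p2 = np.ones(pot.shape, dtype=bool)
    for ce_layer in ensemble.layers.values():
        ce = ce_layer.cost_effectiveness
        p1 &= _top_mask(ce, pot, q)
        p2 &= _top_mask(ce, pot & ~ensemble.pa_mask, q)
    p1 &= ~ensemble.uncertainty_mask
    p2 &= ~ensemble.uncertainty_mask & ~ensemble.pa_mask
    return PriorityMap(priority1=p1, priority2=p2, quantile=q)


def _iqr(x: np.ndarray) -> float:
    return float(np.nanpercentile(x, 75) - np.nanpercentile(x, 25)) if x.size else np.nan


def _group_stats(sel: np.ndarray, ens: EnsembleResult, scenario: str) -> dict:
    out = {}
    for label in (HORIZON_5Y, HORIZON_FULL):
        ce_layer = ens.layers[(scenario, label)]
        for stat, arr in (
            ("cost", ce_layer.cost_usd),
            ("gain", ce_layer.agb_gain),
            ("ce", ce_layer.cost_effectiveness),
        ):
            v = arr[sel]
            v = v[np.isfinite(v)]
            out[f"{stat}_{label}_median"] = float(np.median(v)) if v.size else np.nan
            out[f"{stat}_{label}_iqr"] = _iqr(v)
            if stat == "gain":
                out[f"{stat}_{label}_mean"] = float(np.mean(v)) if v.size else np.nan
                out[f"{stat}_{label}_sd"] = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
    return out


def summarize(ensemble: EnsembleResult, scenario: str = "realistic") -> pd.DataFrame:
    """Table-style summary rows: overall, governance, landcover, method.

    Area percentages are taken over all pixels within each grouping, so
    each group_type's percentages (including the overall row's complement)
    sum to 100.  Cost/gain/CE statistics cover pixels where they are
    defined (restoration potential with an assigned method).
    """
    methods = ensemble.method_map(scenario)
    sil = methods.silviculture_class
    n_pix = methods.method.size
    pot = ensemble.potential_mask
    rows = []

    def add(group_type: str, group: str, sel: np.ndarray) -> None:
        rows.append(
            {
                "group_type": group_type,
                "group": group,
                "area_pct": 100.0 * sel.sum() / n_pix,
                "area_ha": float(sel.sum()),
                **_group_stats(sel, ensemble, scenario),
            }
        )

    add("overall", "restorable", pot)
    add("governance", "PA", ensemble.pa_mask)
    add("governance", "NPA", ~ensemble.pa_mask)
    for code, name in LANDCOVER_NAMES.items():
        add("landcover", name, ensemble.landcover == code)
    for cls_name, cls_code in SILVICULTURE_CODES.items():
        add("silviculture", cls_name, sil == cls_code)
    return pd.DataFrame(rows)
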