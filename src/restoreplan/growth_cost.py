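"""Biomass accumulation, implementation cost and cost-effectiveness.

The growth model is a two-phase piecewise-linear trajectory: recovering
vegetation accumulates AGB at rate ``r1`` until it reaches the proportion
``p20`` of its climatic maximum (the stock expected after ~20 years of
recovery), then at the slower rate ``r2`` until maximum AGB.  Costs follow
a schedule of per-treatment, one-off and shared (economies-of-scale)
components inflated annually; cost-effectiveness is the expected AGB gain
per US$100, with the Table-style annualized-cost convention by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import yaml
from scipy import ndimage

from .method_rules import METHOD_CODES, METHOD_NAMES, MethodMap
from .scenarios import GrowthParams


# ---------------------------------------------------------------- growth

def agc_to_agb(agc, carbon_fraction: float = 0.456):
    """Convert above-ground carbon to biomass (AGC = carbon_fraction x AGB)."""
    if carbon_fraction <= 0:
        raise ValueError("carbon_fraction must be positive")
    agc = np.asarray(agc, dtype=float)
    if np.any(agc < 0):
        raise ValueError("AGC must be non-negative")
    return agc / carbon_fraction


def agb_to_agc(agb, carbon_fraction: float = 0.456):
    agb = np.asarray(agb, dtype=float)
    return agb * carbon_fraction


def agb_gain(current, maximum, g: GrowthParams, horizon_years):
    """Expected AGB gain (Mg ha-1) after ``horizon_years`` of recovery.

    Piecewise-linear: rate ``r1`` while AGB < p20 x maximum, then ``r2``
    until maximum; the gain never exceeds the deficit.  Inputs broadcast;
    ``horizon_years`` may be a scalar or a per-pixel array.
    """
    current, maximum, h = np.broadcast_arrays(
        np.asarray(current, dtype=float),
        np.asarray(maximum, dtype=float),
        np.asarray(horizon_years, dtype=float),
    )
    if np.any(h < 0):
        raise ValueError("horizon must be non-negative")
    knee = g.p20 * maximum
    below = current < knee
    t1 = np.where(below, (knee - current) / g.r1, 0.0)
    gain_below = np.where(h <= t1, g.r1 * h, (knee - current) + g.r2 * (h - t1))
    gain_above = g.r2 * h
    gain = np.where(below, gain_below, gain_above)
    gain = np.minimum(gain, np.maximum(maximum - current, 0.0))
    out = np.maximum(gain, 0.0)
    return float(out) if out.ndim == 0 else out


def years_to_recovery(current, maximum, g: GrowthParams):
    """Years for the trajectory to reach maximum AGB (0 where already there).

    Analytic inversion of the piecewise trajectory; agrees with annual
    stepping simulation to within one time step.
    """
    current, maximum = np.broadcast_arrays(
        np.asarray(current, dtype=float), np.asarray(maximum, dtype=float)
    )
    knee = g.p20 * maximum
    below = current < knee
    t = np.where(
        below,
        (knee - current) / g.r1 + (maximum - knee) / g.r2,
        (maximum - current) / g.r2,
    )
    out = np.where(current >= maximum, 0.0, t)
    return float(out) if out.ndim == 0 else out


def years_until_deficit_below(current, maximum, g: GrowthParams, pct_threshold):
    """Years until percent deficit drops below ``pct_threshold``.

    Used to size the active-management period of ANR: intervention continues
    until the pixel's trajectory crosses its ANR onset threshold.  Returns 0
    where the deficit is already below the threshold; pixels with zero
    maximum return 0.
    """
    current, maximum = np.broadcast_arrays(
        np.asarray(current, dtype=float), np.asarray(maximum, dtype=float)
    )
    target = (1.0 - np.asarray(pct_threshold, dtype=float) / 100.0) * maximum
    target = np.minimum(target, maximum)
    knee = g.p20 * maximum
    below_knee = current < knee
    # time to reach `target` from `current` along the two-phase trajectory
    t_phase1 = np.where(below_knee, (np.minimum(target, knee) - current) / g.r1, 0.0)
    t_phase2 = np.where(
        target > knee,
        (target - np.maximum(current, knee)) / g.r2,
        0.0,
    )
    t = np.maximum(t_phase1, 0.0) + np.maximum(t_phase2, 0.0)
    t = np.where(current >= target, 0.0, t)
    t = np.where(maximum <= 0, 0.0, t)
    return float(t) if t.ndim == 0 else t


# ---------------------------------------------------------------- costs

@dataclass(frozen=True)
class MethodCost:
    """Cost components (USD) for one restoration method.

    Shared components scale with the contiguous same-method patch area up
    to a service cap: the per-hectare share of a unit cost ``C`` serving up
    to ``A_max`` ha is ``C / min(patch_area, A_max)``.
    """

    land_procurement: float = 0.0  # USD ha-1, one-off, waived inside PAs
    treatment_cost: float = 0.0  # USD ha-1 per treatment
    treatments_per_year: float = 0.0
    active_years: float = 0.0  # default active-management period
    nursery_cost: float = 0.0  # USD per nursery (planting methods)
    nursery_service_area: float = 1.0  # ha served by one nursery
    transport_cost_per_visit: float = 0.0  # USD per site visit
    visits_per_year: float = 0.0
    transport_service_area: float = 1.0  # ha serviced per visit
    staff_cost_per_year: float = 0.0  # USD yr-1 per oversight unit
    oversight_area: float = 1.0  # ha overseen by one staff unit


@dataclass
class CostSchedule:
    """Full cost schedule: per-method components plus landscape-wide terms."""

    methods: Dict[str, MethodCost]
    community_engagement_per_ha_yr: float = 0.0  # near settlements, outside PAs
    engagement_distance_m: float = 2000.0
    admin_overhead: float = 0.15  # fraction of subtotal

    def __post_init__(self) -> None:
        if not 0.0 <= self.admin_overhead <= 1.0:
            raise ValueError("admin_overhead must be in [0, 1]")
        for name, mc in self.methods.items():
            for f, v in mc.__dict__.items():
                if v < 0:
                    raise ValueError(f"{name}.{f} must be >= 0")
            if min(mc.nursery_service_area, mc.transport_service_area, mc.oversight_area) <= 0:
                raise ValueError(f"{name}: service/oversight areas must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "CostSchedule":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CostSchedule":
        rate = float(raw.get("exchange_rate_tzs_per_usd", 1.0))
        scale = 1.0 / rate if raw.get("currency", "USD") == "TZS" else 1.0
        methods = {}
        for name, comp in raw["methods"].items():
            kwargs = {}
            for k, v in comp.items():
                if k.endswith("_area") or k in ("treatments_per_year", "visits_per_year", "active_years"):
                    kwargs[k] = float(v)
                else:
                    kwargs[k] = float(v) * scale
            methods[name] = MethodCost(**kwargs)
        return cls(
            methods=methods,
            community_engagement_per_ha_yr=float(raw.get("community_engagement_per_ha_yr", 0.0)) * scale,
            engagement_distance_m=float(raw.get("engagement_distance_m", 2000.0)),
            admin_overhead=float(raw.get("admin_overhead", 0.15)),
        )


@dataclass(frozen=True)
class EconomyParams:
    """Exchange rate and inflation applied to the cost schedule."""

    exchange_rate_tzs_per_usd: float = 2326.0
    inflation: float = 0.022  # fraction per year
    def __post_init__(self) -> None:
        if self.exchange_rate_tzs_per_usd <= 0:
            raise ValueError("exchange rate must be positive")
        if self.inflation < 0:
            raise ValueError("inflation must be >= 0")


def _patch_area(method: np.ndarray, code: int, cell_area_ha: float) -> np.ndarray:
    """Contiguous same-method patch area (ha) at each pixel of that method."""
    mask = method == code
    labels, n = ndimage.label(mask)
    area = np.zeros(method.shape, dtype=float)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        area[mask] = sizes[labels[mask] - 1] * cell_area_ha
    return area


def compute_cost(
    method_map: MethodMap,
    pa_mask: np.ndarray,
    settlement_dist: np.ndarray,
    schedule: CostSchedule,
    econ: EconomyParams,
    horizon_years,
    active_years: Optional[np.ndarray] = None,
    cell_area_ha: float = 1.0,
) -> np.ndarray:
    """Annualized restoration cost (USD ha-1 yr-1) per pixel.

    Year ``t`` (1-based) incurs: treatment and transport costs while
    ``t <= active_years``; staff oversight and community engagement (near
    settlements, outside protected areas) every year; land procurement
    (outside protected areas) and the nursery share once in year 1.  Annual
    totals are inflated by ``(1 + inflation)^(t-1)``, administrative
    overhead is added as a fraction of the subtotal, and the sum over the
    horizon is divided by the horizon.  Shared components are divided by
    the contiguous same-method patch area capped at their service areas.

    ``horizon_years`` and ``active_years`` may be scalars or per-pixel
    arrays; pixels with method ``none`` return NaN.
    """
    method = method_map.method
    pa_mask = np.asarray(pa_mask, dtype=bool)
    settlement_dist = np.asarray(settlement_dist, dtype=float)
    horizon = np.broadcast_to(np.asarray(horizon_years, dtype=float), method.shape)
    if np.any(horizon[method != METHOD_CODES["none"]] <= 0):
        raise ValueError("horizon must be positive on treated pixels")

    present = [int(c) for c in np.unique(method) if c != METHOD_CODES["none"]]
    missing = [METHOD_NAMES[c] for c in present if METHOD_NAMES[c] not in schedule.methods]
    if missing:
        raise KeyError(f"cost schedule lacks methods: {missing}")

    one_off = np.zeros(method.shape)
    annual_active = np.zeros(method.shape)
    annual_always = np.zeros(method.shape)
    default_active = np.zeros(method.shape)

    for code in present:
        mc = schedule.methods[METHOD_NAMES[code]]
        sel = method == code
        patch = _patch_area(method, code, cell_area_ha)
        eff_nursery = np.minimum(np.where(sel, patch, 1.0), mc.nursery_service_area)
        eff_transport = np.minimum(np.where(sel, patch, 1.0), mc.transport_service_area)
        eff_staff = np.minimum(np.where(sel, patch, 1.0), mc.oversight_area)

        one_off[sel] += np.where(pa_mask[sel], 0.0, mc.land_procurement)
        if mc.nursery_cost:
            one_off[sel] += mc.nursery_cost / eff_nursery[sel]
        annual_active[sel] += mc.treatment_cost * mc.treatments_per_year
        if mc.transport_cost_per_visit:
            annual_active[sel] += (
                mc.transport_cost_per_visit * mc.visits_per_year / eff_transport[sel]
            )
        if mc.staff_cost_per_year:
            annual_always[sel] += mc.staff_cost_per_year / eff_staff[sel]
        default_active[sel] = mc.active_years

    engaged = (settlement_dist <= schedule.engagement_distance_m) & ~pa_mask
    annual_always += np.where(engaged, schedule.community_engagement_per_ha_yr, 0.0)

    act = default_active if active_years is None else np.asarray(active_years, dtype=float)
    act = np.broadcast_to(act, method.shape)
    act = np.minimum(act, horizon)

    t_max = int(np.ceil(np.nanmax(horizon[np.isfinite(horizon)], initial=1.0)))
    total = one_off.copy()
    for t in range(1, t_max + 1):
        infl = (1.0 + econ.inflation) ** (t - 1)
        in_horizon = t <= np.ceil(horizon)
        # fraction of year t inside the horizon (partial final year)
        frac = np.clip(horizon - (t - 1), 0.0, 1.0)
        active_frac = np.clip(act - (t - 1), 0.0, 1.0)
        total += infl * frac * annual_always * in_horizon
        total += infl * np.minimum(frac, active_frac) * annual_active * in_horizon

    total *= 1.0 + schedule.admin_overhead
    with np.errstate(divide="ignore", invalid="ignore"):
        annualized = total / horizon
    annualized[method == METHOD_CODES["none"]] = np.nan
    return annualized


def cost_effectiveness(gain, cost, per_dollars: float = 100.0):
    """AGB gain per ``per_dollars`` US$ (Eq. AGB$ = dAGB / $).

    ``cost`` follows whatever convention the caller uses — the pipeline
    passes annualized USD ha-1 yr-1 (the tabulated convention), giving Mg
    per US$100 per year of funding; pass cumulative cost for gain per total
    dollar.  Non-positive or missing cost yields NaN with a warning.
    """
    gain = np.asarray(gain, dtype=float)
    cost = np.asarray(cost, dtype=float)
    bad = ~(cost > 0)
    if bad.any() and np.isfinite(gain[bad]).any():
        warnings.warn("cost <= 0 or missing: cost-effectiveness undefined there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ce = np.where(cost > 0, per_dollars * gain / cost, np.nan)
    return float(ce) if ce.ndim == 0 else ce


@dataclass
class CEResult:
    """Gain, cost and cost-effectiveness rasters for one scenario x horizon."""

    scenario: str
    horizon: str  # "5y" or "full"
    agb_gain: np.ndarray
    cost_usd: np.ndarray  # annualized USD ha-1 yr-1
    cost_effectiveness: np.ndarray  # Mg per US$100 (annualized-cost convention)
    method_map: MethodMap = field(repr=False, default=None)
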