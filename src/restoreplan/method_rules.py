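"""Biomass deficit and rule-based restoration-method assignment.

Per hectare pixel with a positive AGB deficit, the most appropriate
silvicultural approach is selected from a threshold framework over percent
deficit, landcover class, elevation and Euclidean distances to intact and
disturbed habitat.  Precedence follows degradation severity: soil
improvement + nurse planting > framework planting > assisted natural
regeneration (ANR) > passive regeneration; within forest ANR the invasive
Lantana-removal rule is the most specific and wins inside its envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import ndimage

from .grids import LANDCOVER_CODES
from .scenarios import ScenarioParams

METHOD_CODES: Dict[str, int] = {
    "none": 0,
    "passive": 1,
    "vine_cutting": 2,
    "herb_shrub_cutting": 3,
    "lantana_removal": 4,
    "firebreak_and_grass_cutting": 5,
    "framework_planting": 6,
    "soil_improvement_nurse_planting": 7,
}
METHOD_NAMES: Dict[int, str] = {v: k for k, v in METHOD_CODES.items()}

SILVICULTURE_CODES: Dict[str, int] = {"none": 0, "passive": 1, "anr": 2, "planting": 3}

#: method code -> silviculture class code
METHOD_TO_CLASS: Dict[int, int] = {
    METHOD_CODES["none"]: SILVICULTURE_CODES["none"],
    METHOD_CODES["passive"]: SILVICULTURE_CODES["passive"],
    METHOD_CODES["vine_cutting"]: SILVICULTURE_CODES["anr"],
    METHOD_CODES["herb_shrub_cutting"]: SILVICULTURE_CODES["anr"],
    METHOD_CODES["lantana_removal"]: SILVICULTURE_CODES["anr"],
    METHOD_CODES["firebreak_and_grass_cutting"]: SILVICULTURE_CODES["anr"],
    METHOD_CODES["framework_planting"]: SILVICULTURE_CODES["planting"],
    METHOD_CODES["soil_improvement_nurse_planting"]: SILVICULTURE_CODES["planting"],
}

_FOREST = LANDCOVER_CODES["moist_forest"]
_SAVANNA_LIKE = (
    LANDCOVER_CODES["savanna"],
    LANDCOVER_CODES["floodplain"],
    LANDCOVER_CODES["agro_mosaic"],
)


@dataclass
class DeficitMap:
    """Absolute (Mg ha-1) and percent AGB deficit, and restoration potential.

    ``percent`` is 100 x (maximum - current) / maximum, NaN where maximum
    is zero or no-data.  ``potential_mask`` is True exactly where the
    absolute deficit is positive: pixels at or above their climatic maximum
    are assumed to have gained or held AGB and are excluded from planning.
    """

    absolute: np.ndarray
    percent: np.ndarray
    potential_mask: np.ndarray


def compute_deficit(current: np.ndarray, maximum: np.ndarray) -> DeficitMap:
    current = np.asarray(current, dtype=float)
    maximum = np.asarray(maximum, dtype=float)
    if current.shape != maximum.shape:
        raise ValueError("current and maximum rasters are misaligned")
    absolute = maximum - current
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(maximum > 0, 100.0 * absolute / maximum, np.nan)
    potential = np.isfinite(percent) & (absolute > 0)
    return DeficitMap(absolute=absolute, percent=percent, potential_mask=potential)


def distance_to(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (m) from each pixel centre to the nearest True pixel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("distance_to: mask has no True pixels")
    return ndimage.distance_transform_edt(~mask, sampling=cell_size)


def passive_threshold_layer(landcover: np.ndarray, scenario: ScenarioParams) -> np.ndarray:
    """Per-pixel passive-regeneration threshold (% deficit) by landcover."""
    landcover = np.asarray(landcover)
    known = np.isin(landcover, [_FOREST, *_SAVANNA_LIKE])
    if not known.all():
        bad = np.unique(landcover[~known])
        raise ValueError(f"unknown landcover codes: {bad.tolist()}")
    thr = np.where(
        landcover == _FOREST,
        scenario.forest_passive_below,
        scenario.savanna_passive_below,
    )
    return thr.astype(float)


def intact_mask(
    deficit: DeficitMap, landcover: np.ndarray, scenario: ScenarioParams
) -> np.ndarray:
    """True where percent deficit is below the landcover passive threshold.

    Pixels with undefined percent deficit (zero maximum) are not intact.
    """
    thr = passive_threshold_layer(landcover, scenario)
    with np.errstate(invalid="ignore"):
        return np.isfinite(deficit.percent) & (deficit.percent < thr)


@dataclass
class MethodMap:
    """Categorical method raster and its silviculture-class reduction."""

    method: np.ndarray  # int codes, METHOD_CODES
    scenario: str

    @property
    def silviculture_class(self) -> np.ndarray:
        out = np.zeros_like(self.method)
        for code, cls in METHOD_TO_CLASS.items():
            out[self.method == code] = cls
        return out

    def class_mask(self, name: str) -> np.ndarray:
        return self.silviculture_class == SILVICULTURE_CODES[name]


def assign_methods(
    deficit: DeficitMap,
    landcover: np.ndarray,
    elevation: np.ndarray,
    dist_intact: np.ndarray,
    dist_disturbed: np.ndarray,
    scenario: ScenarioParams,
) -> MethodMap:
    """Assign a restoration method to every pixel under one scenario.

    Precedence per pixel with restoration potential:

    1. soil improvement + nurse planting where percent deficit is at or
       above the severe-degradation threshold;
    2. framework planting where deficit is in the planting band and the
       pixel is at least the scenario's minimum distance from intact
       habitat (closer pixels are assumed reachable by seed dispersal);
    3. ANR where deficit reaches the landcover ANR onset — in forest,
       Lantana removal (low elevation near disturbance, where the rule is
       enabled), else vine cutting below 1000 m, else herb/shrub cutting;
       in savanna, agro-mosaic and floodplain, a joint firebreak + grass
       cutting treatment;
    4. passive regeneration otherwise.

    Pixels without potential get method ``none``.
    """
    shapes = {
        a.shape
        for a in (
            deficit.percent,
            np.asarray(landcover),
            np.asarray(elevation),
            np.asarray(dist_intact),
            np.asarray(dist_disturbed),
        )
    }
    if len(shapes) != 1:
        raise ValueError("input layers are misaligned")

    landcover = np.asarray(landcover)
    elevation = np.asarray(elevation, dtype=float)
    dist_intact = np.asarray(dist_intact, dtype=float)
    dist_disturbed = np.asarray(dist_disturbed, dtype=float)
    pct = deficit.percent
    pot = deficit.potential_mask
    thr = passive_threshold_layer(landcover, scenario)

    method = np.zeros(pct.shape, dtype=np.int16)
    with np.errstate(invalid="ignore"):
        soil = pot & (pct >= scenario.soil_nurse_at_or_above)
        planting = (
            pot
            & ~soil
            & (pct >= scenario.planting_lower)
            & (pct < scenario.planting_upper)
            & (dist_intact >= scenario.planting_dist_min_from_intact)
        )
        anr = pot & ~soil & ~planting & (pct >= thr)

    forest = landcover == _FOREST
    lantana = (
        anr
        & forest
        & (elevation < scenario.lantana_elev_below)
        & (
            (dist_disturbed <= scenario.lantana_dist_max)
            if scenario.lantana_dist_max is not None
            else False
        )
    )
    vine = anr & forest & ~lantana & (elevation < scenario.vine_cut_elev_below)
    herb = anr & forest & ~lantana & ~vine
    fire = anr & ~forest

    passive = pot & ~soil & ~planting & ~anr

    method[passive] = METHOD_CODES["passive"]
    method[vine] = METHOD_CODES["vine_cutting"]
    method[herb] = METHOD_CODES["herb_shrub_cutting"]
    method[lantana] = METHOD_CODES["lantana_removal"]
    method[fire] = METHOD_CODES["firebreak_and_grass_cutting"]
    method[planting] = METHOD_CODES["framework_planting"]
    method[soil] = METHOD_CODES["soil_improvement_nurse_planting"]
    return MethodMap(method=method, scenario=scenario.name)
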