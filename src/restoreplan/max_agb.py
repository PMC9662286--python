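"""Climate-constrained maximum AGB modelling and extrapolation uncertainty.

Maximum AGB — the biomass a pixel could carry if managed towards a climax
ecosystem — is modelled from closed-canopy reference plots related to
climate predictors only (human influence makes climate uninformative for
*current* AGB, but it bounds the attainable maximum).  Reference plots are
supplemented with pixels sampled from the current-AGB map in
under-represented closed-canopy strata.  Envelope uncertainty maps (EUMs)
flag pixels where any retained climate predictor falls outside the
calibration range extended by a tolerance fraction of that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from .agb_mapping import AgbModel, PredictorSet, fit_agb_model, screen_predictors
from .grids import LANDCOVER_CODES, LandscapeStack

#: elevation (m) below which forest counts as "lowland" for stratified supplements
LOWLAND_ELEVATION_M = 800.0


@dataclass
class ReferenceSet:
    """Closed-canopy calibration records for the maximum-AGB model.

    ``records`` holds plot-derived rows; ``supplements`` holds pixel samples
    whose AGB is read from the current-AGB map.  Both carry row/col/agb and
    a stratum label and are concatenated by :meth:`table`.
    """

    records: pd.DataFrame
    supplements: pd.DataFrame = field(default_factory=pd.DataFrame)

    def table(self) -> pd.DataFrame:
        frames = [f for f in (self.records, self.supplements) if len(f)]
        return pd.concat(frames, ignore_index=True)

    def __len__(self) -> int:
        return len(self.records) + len(self.supplements)


def build_reference_set(
    plots: pd.DataFrame,
    current_agb: np.ndarray,
    stack: LandscapeStack,
    counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Closed-canopy plots plus stratified random pixel supplements.

    ``counts`` maps stratum name to the number of supplement pixels, e.g.
    ``{"savanna": 33, "lowland_forest": 10}``.  Strata are defined on the
    landcover layer (``lowland_forest`` additionally requires elevation
    below 800 m) intersected with closed-canopy condition (degradation
    below the closed-canopy cutoff, read from the truth layer when present,
    otherwise all stratum pixels are eligible).  Supplement AGB comes from
    ``current_agb`` with no added noise.
    """
    counts = dict(counts or {})
    closed = plots.loc[plots["closed_canopy"]].copy()
    records = closed[["row", "col", "agb"]].copy()
    records["stratum"] = "plot"

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    landcover = stack["landcover"]
    supp_frames: List[pd.DataFrame] = []
    for stratum, n in counts.items():
        if n == 0:
            continue
        if stratum == "lowland_forest":
            mask = (landcover == LANDCOVER_CODES["moist_forest"]) & (
                stack["elevation"] < LOWLAND_ELEVATION_M
            )
        elif stratum in LANDCOVER_CODES:
            mask = landcover == LANDCOVER_CODES[stratum]
        else:
            raise KeyError(f"unknown stratum {stratum!r}")
        if "degradation" in stack:
            from .synthetic import CLOSED_CANOPY_DEGRADATION_CUTOFF

            mask = mask & (stack["degradation"] < CLOSED_CANOPY_DEGRADATION_CUTOFF)
        pool = np.flatnonzero(mask.ravel())
        if pool.size < n:
            raise ValueError(
                f"stratum {stratum!r} has {pool.size} eligible pixels, {n} requested"
            )
        idx = rng.choice(pool, size=n, replace=False)
        r, c = np.unravel_index(idx, landcover.shape)
        supp_frames.append(
            pd.DataFrame({"row": r, "col": c, "agb": current_agb[r, c], "stratum": stratum})
        )

    supplements = (
        pd.concat(supp_frames, ignore_index=True) if supp_frames else pd.DataFrame()
    )
    return ReferenceSet(records=records, supplements=supplements)


def climate_predictors_at(
    stack: LandscapeStack, rows: np.ndarray, cols: np.ndarray
) -> PredictorSet:
    names = sorted(n for n in stack.names() if n.startswith("clim"))
    values = np.column_stack([stack[n][rows, cols] for n in names])
    return PredictorSet(names=names, values_at_plots=values)


def fit_max_agb(
    reference: ReferenceSet,
    stack: LandscapeStack,
    screen_threshold: float = 0.6,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    seed: int = 0,
) -> tuple[AgbModel, "EnvelopeTable"]:
    """Fit the climate -> maximum AGB random forest.

    Uses the same screening rule and cross-validation design as the
    current-AGB model.  Also returns the calibration envelope (per-predictor
    min/max over the reference records) for uncertainty mapping.
    """
    table = reference.table()
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()
    y = table["agb"].to_numpy(dtype=float)
    cands = climate_predictors_at(stack, rows, cols)
    screened = screen_predictors(cands, y, threshold=screen_threshold)
    model = fit_agb_model(
        y, screened, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed
    )
    envelope = EnvelopeTable.from_calibration(screened)
    return model, envelope


@dataclass
class EnvelopeTable:
    """Calibration range per retained climate predictor.

    ``level`` is the tolerated extrapolation as a fraction of each
    predictor's calibration range: a pixel is inside the envelope for a
    predictor while its value lies in [min - level*range, max + level*range].
    """

    minima: Dict[str, float]
    maxima: Dict[str, float]
    level: float = 0.1

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("level must be >= 0")
        for n in self.minima:
            if self.minima[n] > self.maxima[n]:
                raise ValueError(f"envelope for {n!r} has min > max")

    @classmethod
    def from_calibration(cls, predictors: PredictorSet, level: float = 0.1) -> "EnvelopeTable":
        mins = {
            n: float(predictors.values_at_plots[:, j].min())
            for j, n in enumerate(predictors.names)
        }
        maxs = {
            n: float(predictors.values_at_plots[:, j].max())
            for j, n in enumerate(predictors.names)
        }
        return cls(minima=mins, maxima=maxs, level=level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.minima),
                "cal_min": [self.minima[n] for n in self.minima],
                "cal_max": [self.maxima[n] for n in self.minima],
                "level": self.level,
            }
        )


def envelope_uncertainty(
    stack: LandscapeStack, envelope: EnvelopeTable, level: float | None = None
) -> np.ndarray:
    """Boolean raster: True where any enveloped predictor is extrapolated.

    A pixel is flagged iff, for at least one predictor in the envelope, its
    value lies outside [min - level*range, max + level*range] with
    range = max - min.  Increasing ``level`` can only clear flags, never
    set new ones.
    """
    lvl = envelope.level if level is None else level
    if lvl < 0:
        raise ValueError("level must be >= 0")
    flagged = np.zeros(stack.grid.shape, dtype=bool)
    for name, lo in envelope.minima.items():
        if name not in stack:
            raise KeyError(f"predictor {name!r} missing from stack")
        hi = envelope.maxima[name]
        rng = hi - lo
        vals = stack[name]
        flagged |= (vals < lo - lvl * rng) | (vals > hi + lvl * rng)
    return flagged
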