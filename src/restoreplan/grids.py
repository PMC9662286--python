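"""Grid definitions and raster containers shared by every pipeline stage.

All layers in a :class:`LandscapeStack` are 2-D numpy arrays on one fine
grid (default 25 m cells).  Hectare-scale analysis layers are produced by
block aggregation with :func:`aggregate_block`, where one hectare cell is
``aggregation_factor × aggregation_factor`` fine cells (default 4 × 4,
i.e. 100 m × 100 m = 1 ha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Definition of the fine analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Fine-grid dimensions; both must be divisible by ``aggregation_factor``.
    cell_size
        Fine cell edge length in metres (default 25 m).
    origin
        (x, y) of the upper-left corner in projected coordinates.
    aggregation_factor
        Fine cells per side of one hectare cell; ``cell_size *
        aggregation_factor`` must equal 100 m so an aggregated cell is 1 ha.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 25.0
    origin: Tuple[float, float] = (0.0, 0.0)
    aggregation_factor: int = 4

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.aggregation_factor < 1:
            raise ValueError("aggregation_factor must be >= 1")
        if self.n_rows % self.aggregation_factor or self.n_cols % self.aggregation_factor:
            raise ValueError(
                "n_rows and n_cols must be divisible by aggregation_factor"
            )
        if abs(self.cell_size * self.aggregation_factor - 100.0) > 1e-9:
            raise ValueError("cell_size * aggregation_factor must equal 100 m")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def hectare_shape(self) -> Tuple[int, int]:
        f = self.aggregation_factor
        return (self.n_rows // f, self.n_cols // f)

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size / 100.0) ** 2

    def hectare_grid(self) -> "GridSpec":
        """The 100 m (1 ha) grid aligned with this fine grid."""
        f = self.aggregation_factor
        return GridSpec(
            n_rows=self.n_rows // f,
            n_cols=self.n_cols // f,
            cell_size=self.cell_size * f,
            origin=self.origin,
            aggregation_factor=1,
        )


# integer codes for the landcover raster
LANDCOVER_CODES: Dict[str, int] = {
    "moist_forest": 1,
    "savanna": 2,
    "floodplain": 3,
    "agro_mosaic": 4,
}
LANDCOVER_NAMES: Dict[int, str] = {v: k for k, v in LANDCOVER_CODES.items()}


@dataclass
class LandscapeStack:
    """Aligned raster layers sharing one :class:`GridSpec`.

    ``layers`` maps layer name -> 2-D array with shape ``grid.shape``.
    Synthetic stacks also carry truth layers (``current_agb_true``,
    ``max_agb_true``, ``degradation``) used only by tests and validation.
    """

    grid: GridSpec
    layers: Dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
            )
        self.layers[name] = arr

    def names(self):
        return list(self.layers)


def _blocks(arr: np.ndarray, factor: int) -> np.ndarray:
    r, c = arr.shape
    if r % factor or c % factor:
        raise ValueError("array dimensions not divisible by aggregation factor")
    return arr.reshape(r // factor, factor, c // factor, factor)


def aggregate_block(arr: np.ndarray, factor: int, how: str = "mean") -> np.ndarray:
    """Aggregate a fine raster into blocks of ``factor x factor`` cells.

    ``how='mean'`` averages densities (for Mg ha-1 layers this equals the
    sum of per-cell stocks expressed per hectare, so landscape totals are
    conserved); ``'any'``/``'all'`` combine boolean masks; ``'mode'`` takes
    the most frequent value (ties -> smallest code) for categorical layers.
    NaNs propagate through 'mean' only where a whole block is NaN.
    """
    b = _blocks(np.asarray(arr), factor)
    if how == "mean":
        with np.errstate(invalid="ignore"):
            return np.nanmean(b.astype(float), axis=(1, 3))
    if how == "sum":
        return np.nansum(b.astype(float), axis=(1, 3))
    if how == "any":
        return b.astype(bool).any(axis=(1, 3))
    if how == "all":
        return b.astype(bool).all(axis=(1, 3))
    if how == "mode":
        flat = b.transpose(0, 2, 1, 3).reshape(b.shape[0], b.shape[2], -1)
        codes = np.unique(flat)
        counts = np.stack([(flat == c).sum(axis=-1) for c in codes], axis=-1)
        return codes[np.argmax(counts, axis=-1)]
    raise ValueError(f"unknown aggregation {how!r}")
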