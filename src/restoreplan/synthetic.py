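"""Seeded synthetic landscapes with the statistical structure the pipeline assumes.

The generator emulates the inputs of a landscape restoration assessment in
an East-African forest/savanna mosaic: smooth spatially autocorrelated
climate surfaces, a climate-constrained maximum above-ground biomass (AGB)
surface, a degradation field elevated near roads and settlements, the
resulting current AGB, spectral reflectance bands that respond monotonically
to current AGB, landcover classes, elevation, and protected-area /
road / settlement masks.  Truth layers are retained so downstream model
fits can be validated against the generating functions.

Every array is reproducible bit-for-bit from ``SyntheticConfig.seed``; all
stage-level randomness is drawn from children of one ``SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, LandscapeStack, LANDCOVER_CODES

#: degradation below which a pixel counts as closed canopy for plot sampling
CLOSED_CANOPY_DEGRADATION_CUTOFF = 0.2

#: metres around roads/settlements within which degradation is elevated
DISTURBANCE_BUFFER_M = 500.0

#: AGB scale (Mg ha-1) used to normalise the band response curves
_AGB_SCALE = 300.0

# Saturating (Michaelis-Menten) reflectance responses: red/SWIR darken with
# biomass, near-infrared brightens.  (intercept, amplitude, half-saturation)
BAND_PARAMS = {
    "band_red": (0.14, -0.10, 0.25),
    "band_nir": (0.18, +0.14, 0.35),
    "band_swir1": (0.25, -0.18, 0.30),
    "band_swir2": (0.20, -0.15, 0.20),
}
BAND_NAMES = list(BAND_PARAMS)

#: weights of the six climate fields that enter the true maximum-AGB surface;
#: the first two dominate, mirroring landscapes where dry-season temperature
#: and water deficit control woody biomass.
MAX_AGB_WEIGHTS = (1.0, 0.8, 0.35, 0.25, 0.2, 0.15)
N_SIGNAL_CLIMATE = len(MAX_AGB_WEIGHTS)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic landscape generator.

    Defaults represent a moderately degraded tropical mosaic: mean
    degradation ~0.35 (so mean percent AGB deficit ~35%), ~30% of the area
    protected, 195 vegetation plots with 10 Mg ha-1 measurement noise, and
    low-noise reflectance (band noise 0.01 reflectance units against band
    amplitudes of 0.10-0.18).
    """

    seed: int = 0
    climate_field_count: int = 19
    spatial_correlation_length: float = 1000.0  # metres
    degradation_intensity: float = 0.35
    road_density: float = 0.08  # lines per km^2
    pa_fraction: float = 0.30
    plot_count: int = 195
    plot_noise_sd: float = 10.0  # Mg ha-1
    band_noise_sd: float = 0.01  # reflectance units

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation_intensity <= 1.0:
            raise ValueError("degradation_intensity must be in [0, 1]")
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise ValueError("pa_fraction must be in [0, 1]")
        if self.plot_count < 10:
            raise ValueError("plot_count must be >= 10")
        if self.climate_field_count < N_SIGNAL_CLIMATE:
            raise ValueError(
                f"need at least {N_SIGNAL_CLIMATE} climate fields"
            )


def _smooth_field(shape, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian random field: white noise filtered with a
    Gaussian kernel of width ``sigma_cells``, then rescaled to mean 0, sd 1."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    if sd == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def true_max_agb(climate: np.ndarray) -> np.ndarray:
    """Deterministic maximum-AGB surface from the six signal climate fields.

    ``climate`` is stacked (6, rows, cols) of standardised fields.  A
    weighted climate score is squashed through a logistic so maximum AGB
    spans ~30 (open savanna) to ~320 Mg ha-1 (moist forest).
    """
    w = np.asarray(MAX_AGB_WEIGHTS)
    s = np.tensordot(w, climate, axes=(0, 0)) / np.linalg.norm(w)
    return 30.0 + 290.0 * _sigmoid(1.4 * s)


def band_response(name: str, agb: np.ndarray) -> np.ndarray:
    """Noise-free reflectance of one band as a function of current AGB."""
    b0, amp, k = BAND_PARAMS[name]
    a = np.asarray(agb, dtype=float) / _AGB_SCALE
    return b0 + amp * a / (a + k)


def _roads_mask(grid: GridSpec, n_lines: int, rng: np.random.Generator) -> np.ndarray:
    from skimage.draw import line

    mask = np.zeros(grid.shape, dtype=bool)
    r, c = grid.shape
    for _ in range(n_lines):
        # random chord: pick points on two distinct edges
        edges = rng.choice(4, size=2, replace=False)
        pts = []
        for e in edges:
            if e == 0:
                pts.append((0, int(rng.integers(c))))
            elif e == 1:
                pts.append((r - 1, int(rng.integers(c))))
            elif e == 2:
                pts.append((int(rng.integers(r)), 0))
            else:
                pts.append((int(rng.integers(r)), c - 1))
        rr, cc = line(pts[0][0], pts[0][1], pts[1][0], pts[1][1])
        mask[rr, cc] = True
    return mask


def _settlements_mask(grid: GridSpec, n_blobs: int, rng: np.random.Generator) -> np.ndarray:
    from skimage.draw import disk

    mask = np.zeros(grid.shape, dtype=bool)
    r, c = grid.shape
    for _ in range(n_blobs):
        centre = (int(rng.integers(r)), int(rng.integers(c)))
        radius = int(rng.integers(2, max(3, min(r, c) // 20)))
        rr, cc = disk(centre, radius, shape=grid.shape)
        mask[rr, cc] = True
    return mask


def generate_landscape(config: SyntheticConfig, grid: GridSpec) -> LandscapeStack:
    """Generate one aligned synthetic landscape.

    Layers produced (fine grid): ``clim01``..``climNN``, ``elevation``,
    ``landcover`` (integer codes), ``road_mask``, ``settlement_mask``,
    ``pa_mask``, the four reflectance bands, and the truth layers
    ``max_agb_true``, ``degradation`` and ``current_agb_true``.

    The first six climate fields drive :func:`true_max_agb`; the remaining
    fields are nuisance layers strongly correlated (r ~ 0.85) with one of
    the six, so predictor screening has realistic collinearity to remove.
    Degradation is a positive spatially correlated field scaled so its
    landscape mean equals ``degradation_intensity``, then inflated within
    500 m of roads/settlements and clipped to [0, 1].  Current AGB is
    maximum AGB x (1 - degradation).
    """
    ss = np.random.SeedSequence(config.seed)
    (s_clim, s_nuis, s_lc, s_elev, s_road, s_settle, s_degr, s_band, s_pa) = (
        np.random.default_rng(c) for c in ss.spawn(9)
    )

    sigma = config.spatial_correlation_length / grid.cell_size
    stack = LandscapeStack(grid=grid)

    signal = np.stack(
        [_smooth_field(grid.shape, sigma, s_clim) for _ in range(N_SIGNAL_CLIMATE)]
    )
    mix = 0.85
    n_clim = config.climate_field_count
    for i in range(n_clim):
        if i < N_SIGNAL_CLIMATE:
            fld = signal[i]
        else:
            parent = signal[i % N_SIGNAL_CLIMATE]
            indep = _smooth_field(grid.shape, sigma, s_nuis)
            fld = mix * parent + np.sqrt(1 - mix**2) * indep
        stack.add(f"clim{i + 1:02d}", fld)

    max_agb = true_max_agb(signal)
    stack.add("max_agb_true", max_agb)

    # landcover from a moisture proxy (clim01) with categorical noise
    moisture = signal[0] + 0.25 * s_lc.standard_normal(grid.shape)
    landcover = np.full(grid.shape, LANDCOVER_CODES["savanna"], dtype=np.int16)
    landcover[moisture < -0.8] = LANDCOVER_CODES["agro_mosaic"]
    landcover[(moisture >= 0.6) & (moisture < 0.9)] = LANDCOVER_CODES["floodplain"]
    landcover[moisture >= 0.9] = LANDCOVER_CODES["moist_forest"]
    stack.add("landcover", landcover)

    elevation = 100.0 + 2400.0 * _sigmoid(1.2 * _smooth_field(grid.shape, sigma, s_elev))
    stack.add("elevation", elevation)

    area_km2 = grid.n_rows * grid.n_cols * grid.cell_size**2 / 1e6
    n_roads = max(1, int(round(config.road_density * area_km2)))
    roads = _roads_mask(grid, n_roads, s_road)
    settlements = _settlements_mask(grid, max(1, n_roads // 2 + 1), s_settle)
    stack.add("road_mask", roads)
    stack.add("settlement_mask", settlements)

    dist = ndimage.distance_transform_edt(
        ~(roads | settlements), sampling=grid.cell_size
    )
    near = dist <= DISTURBANCE_BUFFER_M

    if config.degradation_intensity == 0.0:
        degradation = np.zeros(grid.shape)
    else:
        w = np.exp(0.6 * _smooth_field(grid.shape, sigma, s_degr)) * (1.0 + 1.5 * near)
        degradation = np.clip(config.degradation_intensity * w / w.mean(), 0.0, 1.0)
    stack.add("degradation", degradation)

    current = max_agb * (1.0 - degradation)
    stack.add("current_agb_true", current)

    for name in BAND_NAMES:
        clean = band_response(name, current)
        noisy = clean + config.band_noise_sd * s_band.standard_normal(grid.shape)
        stack.add(name, np.clip(noisy, 0.0, None))

    pa_field = _smooth_field(grid.shape, sigma, s_pa)
    if config.pa_fraction <= 0:
        pa = np.zeros(grid.shape, dtype=bool)
    elif config.pa_fraction >= 1:
        pa = np.ones(grid.shape, dtype=bool)
    else:
        pa = pa_field >= np.quantile(pa_field, 1.0 - config.pa_fraction)
    stack.add("pa_mask", pa)

    return stack


def sample_plots(
    stack: LandscapeStack,
    n: int,
    closed_canopy_fraction: float | None = None,
    seed: int = 0,
    plot_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Sample ``n`` vegetation plots from a synthetic stack.

    Plots fall uniformly at random on pixels (without replacement); plot AGB
    is the true current AGB plus Gaussian measurement noise (floored at 0).
    The closed-canopy flag is true where degradation is below
    :data:`CLOSED_CANOPY_DEGRADATION_CUTOFF`.  If ``closed_canopy_fraction``
    is given, that share of plots is drawn from the closed-canopy pool
    (falling back to fewer if the pool is smaller).  Plot areas are drawn
    from a Beta(1.3, 2.1) stretched over 0.08-1.00 ha, matching field
    campaigns whose plots average ~0.4 ha.

    Returns a DataFrame with columns ``plot_id, row, col, area, agb,
    closed_canopy, landcover``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = stack.grid
    n_pix = grid.n_rows * grid.n_cols
    if n > n_pix:
        raise ValueError(f"requested {n} plots but grid has only {n_pix} pixels")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    degr = stack["degradation"]
    closed_pool = np.flatnonzero((degr < CLOSED_CANOPY_DEGRADATION_CUTOFF).ravel())
    if closed_canopy_fraction is None:
        idx = rng.choice(n_pix, size=n, replace=False)
    else:
        n_closed = min(int(round(n * closed_canopy_fraction)), closed_pool.size)
        open_pool = np.setdiff1d(np.arange(n_pix), closed_pool, assume_unique=True)
        chosen_closed = rng.choice(closed_pool, size=n_closed, replace=False)
        chosen_open = rng.choice(open_pool, size=n - n_closed, replace=False)
        idx = np.concatenate([chosen_closed, chosen_open])
        rng.shuffle(idx)

    rows, cols = np.unravel_index(idx, grid.shape)
    truth = stack["current_agb_true"][rows, cols]
    sd = plot_noise_sd if plot_noise_sd is not None else _default_plot_noise(stack)
    agb = np.maximum(truth + sd * rng.standard_normal(n), 0.0)
    area = 0.08 + 0.92 * rng.beta(1.3, 2.1, size=n)

    return pd.DataFrame(
        {
            "plot_id": [f"P{i:04d}" for i in range(n)],
            "row": rows,
            "col": cols,
            "area": area,
            "agb": agb,
            "closed_canopy": degr[rows, cols] < CLOSED_CANOPY_DEGRADATION_CUTOFF,
            "landcover": stack["landcover"][rows, cols],
        }
    )


def _default_plot_noise(stack: LandscapeStack) -> float:
    # stacks do not carry their config; default to the SyntheticConfig default
    return SyntheticConfig.__dataclass_fields__["plot_noise_sd"].default


def config_to_dict(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)
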