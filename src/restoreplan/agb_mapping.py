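"""Current above-ground biomass mapping from spectral predictors.

Plot AGB is linked to raw reflectance bands and two moving-window texture
indices per band (average and dissimilarity, 12 candidate predictors in
all) with a random-forest regression.  Collinear predictors are screened
greedily on pairwise Pearson correlation, the model is tuned by repeated
k-fold cross-validation on a 4:1 train/test split, and predictions are
upscaled pixel-wise then aggregated from the 25 m grid to one-hectare
cells by averaging densities (equivalently summing per-cell stocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, RepeatedKFold, train_test_split

from .grids import GridSpec, LandscapeStack, aggregate_block
from .synthetic import BAND_NAMES


def texture_index(band: np.ndarray, window: int = 3, kind: str = "average") -> np.ndarray:
    """Moving-window texture of a reflectance band.

    ``average`` is the window mean.  ``dissimilarity`` is the mean absolute
    difference between the window centre and every pixel in the window — a
    quantization-free analogue of grey-level co-occurrence dissimilarity
    that is exactly reproducible by a per-pixel loop.  Edges are handled by
    reflection padding; the output grid equals the input grid.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2:
        raise ValueError("band must be 2-D")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(band.shape):
        raise ValueError("window larger than raster")
    if not np.all(np.isfinite(band)):
        raise ValueError("band must be finite")

    if kind == "average":
        # scipy's "mirror" is edge-reflection without duplicating the edge
        # pixel, i.e. numpy's pad(mode="reflect")
        return ndimage.uniform_filter(band, size=window, mode="mirror")
    if kind == "dissimilarity":
        pad = window // 2
        padded = np.pad(band, pad, mode="reflect")
        windows = sliding_window_view(padded, (window, window))
        centre = band[:, :, None, None]
        return np.abs(windows - centre).mean(axis=(2, 3))
    raise ValueError(f"unknown texture kind {kind!r}")


@dataclass
class PredictorSet:
    """Named predictors evaluated at plot locations.

    ``values_at_plots`` is (n_plots, n_predictors) aligned with ``names``;
    ``correlation_with_response`` holds each predictor's Pearson r against
    plot AGB (populated by :func:`screen_predictors`).
    """

    names: List[str]
    values_at_plots: np.ndarray
    correlation_with_response: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_at_plots = np.asarray(self.values_at_plots, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("predictor names must be unique")
        if self.values_at_plots.shape[1] != len(self.names):
            raise ValueError("values_at_plots columns must match names")

    def subset(self, names: Sequence[str]) -> "PredictorSet":
        idx = [self.names.index(n) for n in names]
        return PredictorSet(
            names=list(names),
            values_at_plots=self.values_at_plots[:, idx],
            correlation_with_response={
                n: self.correlation_with_response[n]
                for n in names
                if n in self.correlation_with_response
            },
        )


def candidate_predictor_layers(
    stack: LandscapeStack, window: int = 3, bands: Sequence[str] = BAND_NAMES
) -> Dict[str, np.ndarray]:
    """The 12 spectral candidate layers: each band raw, plus its moving-window
    average and dissimilarity textures."""
    layers: Dict[str, np.ndarray] = {}
    for b in bands:
        raw = np.asarray(stack[b], dtype=float)
        layers[b] = raw
        layers[f"{b}_avg"] = texture_index(raw, window, "average")
        layers[f"{b}_dis"] = texture_index(raw, window, "dissimilarity")
    return layers


def predictors_at_plots(
    layers: Dict[str, np.ndarray], plots: pd.DataFrame
) -> PredictorSet:
    rows = plots["row"].to_numpy()
    cols = plots["col"].to_numpy()
    names = list(layers)
    values = np.column_stack([layers[n][rows, cols] for n in names])
    return PredictorSet(names=names, values_at_plots=values)


def screen_predictors(
    candidates: PredictorSet, response: np.ndarray, threshold: float = 0.6
) -> PredictorSet:
    """Greedy collinearity screen.

    Constant predictors (undefined correlation) are dropped with a warning.
    Then, while any retained pair has |pairwise r| >= threshold, the worst
    (largest |r|) pair is resolved by dropping the member with the smaller
    |correlation with response|; ties break by name order (earlier name kept).
    Idempotent: screening a screened set returns it unchanged.
    """
    response = np.asarray(response, dtype=float)
    if len(candidates.names) < 2:
        raise ValueError("need at least 2 candidate predictors")
    if response.size < 3:
        raise ValueError("need at least 3 plots")

    X = candidates.values_at_plots
    keep: List[str] = []
    cols: List[int] = []
    for j, name in enumerate(candidates.names):
        if np.std(X[:, j]) == 0:
            warnings.warn(f"predictor {name!r} is constant; dropped", stacklevel=2)
        else:
            keep.append(name)
            cols.append(j)
    X = X[:, cols]

    with np.errstate(invalid="ignore", divide="ignore"):
        # a constant response yields NaN correlations; ties then resolve by name
        r_resp = {
            n: float(np.corrcoef(X[:, j], response)[0, 1]) for j, n in enumerate(keep)
        }
        corr = np.corrcoef(X, rowvar=False) if len(keep) > 1 else np.ones((1, 1))
    active = list(range(len(keep)))

    while len(active) > 1:
        sub = np.abs(corr[np.ix_(active, active)])
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        a, b = active[i], active[j]
        ra, rb = abs(r_resp[keep[a]]), abs(r_resp[keep[b]])
        if ra > rb:
            drop = b
        elif rb > ra:
            drop = a
        else:  # tie: keep the earlier name
            drop = max(a, b, key=lambda k: keep[k])
        active.remove(drop)

    names = [keep[k] for k in active]
    out = candidates.subset(names)
    out.correlation_with_response = {n: r_resp[n] for n in names}
    return out


@dataclass(frozen=True)
class FitReport:
    """Held-out performance of an AGB regression."""

    r_squared: float
    rmse: float
    cv_folds: int
    cv_repeats: int
    split_ratio: str
    n_train: int
    n_test: int
    retained_predictors: tuple
    seed: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["retained_predictors"] = list(self.retained_predictors)
        return d


@dataclass
class AgbModel:
    """A fitted random-forest AGB model plus its screening outcome."""

    forest: RandomForestRegressor
    predictor_names: List[str]
    report: FitReport


# hyperparameter grid tuned by repeated k-fold CV; the library defaults
# (n_estimators, unlimited depth) are kept, only mtry is searched
_MTRY_GRID = ("sqrt", 1.0)
_N_TREES = 100


def fit_agb_model(
    plots_agb: np.ndarray,
    predictors: PredictorSet,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> AgbModel:
    """Fit a random-forest regression of plot AGB on screened predictors.

    The data are split 4:1 into training and test sets; mtry is tuned on
    the training set with repeated k-fold cross-validation; the report's
    R² and RMSE come from the untouched test fifth.  Identical seeds give
    identical models and reports.
    """
    y = np.asarray(plots_agb, dtype=float)
    X = predictors.values_at_plots
    if y.size < 20:
        raise ValueError("need at least 20 plots")
    if y.size * (1 - test_fraction) < cv_folds:
        raise ValueError("fewer training plots than CV folds")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )
    cv = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    search = GridSearchCV(
        RandomForestRegressor(n_estimators=_N_TREES, random_state=seed, n_jobs=1),
        param_grid={"max_features": list(_MTRY_GRID)},
        cv=cv,
        scoring="neg_root_mean_squared_error",
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    forest = search.best_estimator_

    pred = forest.predict(X_te)
    ss_res = float(np.sum((y_te - pred) ** 2))
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    rmse = float(np.sqrt(np.mean((y_te - pred) ** 2)))

    report = FitReport(
        r_squared=r2,
        rmse=rmse,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        split_ratio=f"{y_tr.size}:{y_te.size}",
        n_train=int(y_tr.size),
        n_test=int(y_te.size),
        retained_predictors=tuple(predictors.names),
        seed=seed,
    )
    return AgbModel(forest=forest, predictor_names=list(predictors.names), report=report)


def fit_current_agb(
    plots: pd.DataFrame,
    stack: LandscapeStack,
    window: int = 3,
    screen_threshold: float = 0.6,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    seed: int = 0,
) -> tuple[AgbModel, Dict[str, np.ndarray]]:
    """Screen the 12 spectral candidates and fit the current-AGB model.

    Returns the fitted model and the candidate layer dict (so the retained
    layers can be fed to :func:`upscale_agb` without recomputation).
    """
    layers = candidate_predictor_layers(stack, window=window)
    cands = predictors_at_plots(layers, plots)
    y = plots["agb"].to_numpy(dtype=float)
    screened = screen_predictors(cands, y, threshold=screen_threshold)
    model = fit_agb_model(y, screened, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed)
    return model, layers


def upscale_agb(model: AgbModel, layers: Dict[str, np.ndarray]) -> np.ndarray:
    """Predict AGB at every pixel from the retained predictor layers.

    No-data (NaN) in any predictor propagates to NaN output; valid
    predictions are bounded by the training response range (an ensemble of
    tree means cannot extrapolate) and are never negative.
    """
    missing = [n for n in model.predictor_names if n not in layers]
    if missing:
        raise KeyError(f"missing predictor layers: {missing}")
    shape = layers[model.predictor_names[0]].shape
    X = np.column_stack(
        [np.asarray(layers[n], dtype=float).ravel() for n in model.predictor_names]
    )
    valid = np.all(np.isfinite(X), axis=1)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = model.forest.predict(X[valid])
    out = out.reshape(shape)
    return np.clip(out, 0.0, None)  # NaN propagates through clip


def aggregate_to_hectare(fine: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Aggregate a fine AGB-density raster (Mg ha-1) to one-hectare cells.

    Each fine cell's density is converted to the stock of its footprint
    (cell_area_ha x density) and the block's stocks are summed, yielding Mg
    per 1 ha cell — numerically the mean of the block's densities, so the
    landscape-total AGB is conserved exactly.
    """
    fine = np.asarray(fine, dtype=float)
    if fine.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    return aggregate_block(fine, grid.aggregation_factor, how="mean")
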