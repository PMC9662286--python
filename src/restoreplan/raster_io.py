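"""File I/O: per-layer TIFF rasters with a sidecar grid definition,
plot tables as CSV, configs as YAML, and the run manifest as JSON.

Each output directory holds one ``<layer>.tif`` per raster (float32, or
uint8 for boolean masks, int16 for categorical codes) and a single
``grid.json`` carrying the shared geotransform-style metadata (origin,
cell size, dimensions), so every layer stays aligned on re-read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import GridSpec, LandscapeStack


def _grid_dict(grid: GridSpec) -> dict:
    return dataclasses.asdict(grid)


def write_grid(directory: Path, grid: GridSpec) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "grid.json"
    path.write_text(json.dumps(_grid_dict(grid), indent=2))
    return path


def read_grid(directory: Path) -> GridSpec:
    d = json.loads((Path(directory) / "grid.json").read_text())
    d["origin"] = tuple(d["origin"])
    return GridSpec(**d)


def write_raster(path: Path, arr: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(arr)
    if arr.dtype == bool:
        data = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        data = arr.astype(np.int16)
    else:
        data = arr.astype(np.float32)
    tifffile.imwrite(path, data)
    return path


def read_raster(path: Path, as_bool: bool = False) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return arr.astype(bool) if as_bool else arr


def write_stack(directory: Path, stack: LandscapeStack) -> None:
    directory = Path(directory)
    write_grid(directory, stack.grid)
    for name, arr in stack.layers.items():
        write_raster(directory / f"{name}.tif", arr)


def read_stack(directory: Path) -> LandscapeStack:
    directory = Path(directory)
    grid = read_grid(directory)
    stack = LandscapeStack(grid=grid)
    bool_layers = {"road_mask", "settlement_mask", "pa_mask"}
    for tif in sorted(directory.glob("*.tif")):
        name = tif.stem
        arr = read_raster(tif, as_bool=name in bool_layers)
        stack.add(name, arr)
    return stack


def write_plots(path: Path, plots: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plots.to_csv(path, index=False)
    return path


def read_plots(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_yaml(path: Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(
    directory: Path, seed: int, config: dict, extra: Optional[dict] = None
) -> Path:
    """JSON run manifest: seed, config hash and package version, so a rerun
    from the manifest reproduces all rasters."""
    from . import __version__

    manifest = {
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "restoreplan_version": __version__,
        **(extra or {}),
    }
    path = Path(directory) / "manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_outputs(
    out_dir: Path,
    ensemble,
    priority,
    summary: pd.DataFrame,
    seed: int,
    config: dict,
) -> Dict[str, Path]:
    """Write the full result set for one pipeline run.

    Rasters: CE per scenario x horizon, the realistic method map, priority
    1/2 and the uncertainty mask; tables: the summary CSV; metadata: the
    JSON manifest.  Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for (scenario, horizon), ce in ensemble.layers.items():
        key = f"ce_{scenario}_{horizon}"
        paths[key] = write_raster(out_dir / f"{key}.tif", ce.cost_effectiveness)
    paths["method_realistic"] = write_raster(
        out_dir / "method_realistic.tif", ensemble.method_map("realistic").method
    )
    paths["priority1"] = write_raster(out_dir / "priority1.tif", priority.priority1)
    paths["priority2"] = write_raster(out_dir / "priority2.tif", priority.priority2)
    paths["uncertainty"] = write_raster(
        out_dir / "uncertainty.tif", ensemble.uncertainty_mask
    )
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False)
    paths["summary"] = summary_path
    from .method_rules import METHOD_CODES

    codes_path = out_dir / "method_codes.json"
    codes_path.write_text(json.dumps(METHOD_CODES, indent=2))
    paths["method_codes"] = codes_path
    paths["manifest"] = write_manifest(out_dir, seed, config)
    return paths
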