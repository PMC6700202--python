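"""Shared I/O plumbing: TIFF images, CSV traces/paths, configs, pipelines.

Images travel as TIFF; this package writes the physical pixel size into the
TIFF's shaped metadata (key ``nm_per_px``) and reads it back, but third-party
TIFFs frequently lack it, so every reader accepts an explicit override and
errors loudly when no pixel size can be resolved. Traces are CSV with columns
``t_s, value``; polyline paths and profile endpoints are CSV in ``(x_px,
y_px)`` column order with x = column index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Image2D, ImageStack, MissingPixelSizeError, PipelineError, Trace
from .tem import CJPath

__all__ = [
    "read_image", "write_image",
    "read_trace", "write_trace",
    "read_paths_csv", "write_paths_csv",
    "read_endpoints_csv",
    "load_config", "write_config_echo",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def read_image(path: Union[str, Path],
               nm_per_px: Optional[float] = None,
               channel_label: str = "") -> Union[Image2D, ImageStack]:
    """Read a single- or multi-page TIFF.

    The pixel size comes from the override if given, else from the file's
    shaped metadata; otherwise a MissingPixelSizeError names the flag to set.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_nmpp = None
        if tif.shaped_metadata:
            meta_nmpp = tif.shaped_metadata[0].get("nm_per_px")
    nmpp = nm_per_px if nm_per_px is not None else meta_nmpp
    if nmpp is None:
        raise MissingPixelSizeError(
            f"{path}: no pixel size in TIFF metadata; pass nm_per_px "
            "(CLI: --nm-per-px)"
        )
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return Image2D(data, float(nmpp), channel_label)
    if data.ndim == 3:
        return ImageStack(data, float(nmpp), channel_label)
    raise PipelineError(f"{path}: unsupported TIFF dimensionality {data.ndim}")


def write_image(path: Union[str, Path],
                img: Union[Image2D, ImageStack]) -> None:
    """Write an image or stack as TIFF with nm_per_px metadata.

    Pixel values are written unchanged (float64), so a write/read round trip
    is bit-exact.
    """
    data = img.pixels if isinstance(img, Image2D) else img.frames
    tifffile.imwrite(
        Path(path), data, photometric="minisblack",
        metadata={"nm_per_px": img.nm_per_px, "channel_label": img.channel_label},
    )


# --------------------------------------------------------------------------
# traces, paths, endpoints
# --------------------------------------------------------------------------

def write_trace(path: Union[str, Path], trace: Trace) -> None:
    df = pd.DataFrame({"t_s": trace.t, "value": trace.f})
    df.to_csv(path, index=False)


def read_trace(path: Union[str, Path],
               baseline_window: Optional[tuple] = None) -> Trace:
    df = pd.read_csv(path)
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise PipelineError(f"{path}: trace CSV needs columns t_s,value")
    return Trace(df["t_s"].to_numpy(float), df["value"].to_numpy(float),
                 baseline_window=baseline_window)


def write_paths_csv(path: Union[str, Path], paths: Sequence[CJPath]) -> None:
    """Polylines as CSV columns: path_id, x_px, y_px (x = column index)."""
    rows = []
    for i, p in enumerate(paths):
        for (x, y) in p.vertices_px:
            rows.append(dict(path_id=i, x_px=x, y_px=y))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths_csv(path: Union[str, Path], nm_per_px: float) -> List[CJPath]:
    df = pd.read_csv(path)
    for col in ("path_id", "x_px", "y_px"):
        if col not in df.columns:
            raise PipelineError(f"{path}: paths CSV needs columns "
                                "path_id,x_px,y_px")
    out = []
    for _, grp in df.groupby("path_id", sort=True):
        out.append(CJPath(grp[["x_px", "y_px"]].to_numpy(float), nm_per_px))
    return out


def read_endpoints_csv(path: Union[str, Path]) -> List[tuple]:
    """Profile endpoint pairs: columns x0_px, y0_px, x1_px, y1_px."""
    df = pd.read_csv(path)
    cols = ("x0_px", "y0_px", "x1_px", "y1_px")
    for col in cols:
        if col not in df.columns:
            raise PipelineError(f"{path}: endpoints CSV needs columns "
                                + ",".join(cols))
    return [((r.x0_px, r.y0_px), (r.x1_px, r.y1_px)) for r in df.itertuples()]


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    return cfg


def config_to_dataclass(cls, cfg: Dict[str, Any]):
    """Instantiate a config dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(cfg) - names
    if unknown:
        raise PipelineError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"valid keys: {sorted(names)}"
        )
    kwargs = dict(cfg)
    # YAML lists -> tuples where dataclasses expect tuples
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return cls(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_config_echo(path: Union[str, Path], resolved: Dict[str, Any]) -> None:
    """Write the fully resolved parameter set next to a run's outputs."""
    with open(path, "w") as fh:
        json.dump(_jsonable(resolved), fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# pipeline runner
# --------------------------------------------------------------------------

def run_pipeline(config: Dict[str, Any]) -> Dict[str, Any]:
    """Execute a sequence of named stages with shared seed and output dir.

    ``config`` keys: ``out_dir`` (str), ``seed`` (int), ``stages`` (list of
    mappings, each with a ``stage`` name plus stage parameters). Stage names
    are validated *before* any computation runs. Per-item failures inside a
    stage (e.g. one bad frame of a time course) are recorded in the outputs
    and do not abort the run. Returns a result bundle keyed by stage index.

    Every run writes ``config_echo.json`` (the resolved parameters) into
    ``out_dir``; numeric outputs land in CSV/JSON.
    """
    from . import pipeline_stages  # deferred: stages import analysis modules

    if "stages" not in config or not config["stages"]:
        raise PipelineError("config needs a non-empty 'stages' list")
    out_dir = Path(config.get("out_dir", "."))
    seed = int(config.get("seed", 0))
    names = [st.get("stage") for st in config["stages"]]
    unknown = [n for n in names if n not in pipeline_stages.STAGES]
    if unknown:
        raise PipelineError(
            f"unknown stage name(s) {unknown}; available: "
            f"{sorted(pipeline_stages.STAGES)}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    write_config_echo(out_dir / "config_echo.json", config)
    bundle: Dict[str, Any] = {}
    context: Dict[str, Any] = {"seed": seed, "out_dir": out_dir}
    for i, st in enumerate(config["stages"]):
        params = {k: v for k, v in st.items() if k != "stage"}
        result = pipeline_stages.STAGES[st["stage"]](context, i, **params)
        bundle[f"{i}:{st['stage']}"] = result
    return bundle
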