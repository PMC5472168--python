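"""Readers and writers: image stacks, shading models, baselines, scores.

Stacks are read from a multi-page TIFF (or any multi-frame image file
imageio can open) or from a directory of single-channel images in natural
sort order.  Shading models are stored as a two-page float32 TIFF
(flat-field, dark-field) with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio

from . import __version__
from .core import BaselineSeries, ImageStack, ShadingModel
from .exceptions import DimensionError, ModelValidityError, ShadingError

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_shading_model",
    "read_shading_model",
    "write_baselines",
    "read_baselines",
]

IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def natural_key(name: str):
    """Sort key treating digit runs numerically: img_2 before img_10."""
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]


def _read_frame(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ShadingError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(arr)


def read_image_stack(path, pattern: str = "*", is_timelapse: bool = False) -> ImageStack:
    """Load an image stack from a multi-page file or a directory.

    Directory entries matching ``pattern`` (with a recognized image
    suffix) are loaded in natural sort order.  All frames must share one
    shape; frames are converted to float, the source dtype is recorded.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.glob(pattern)
             if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file()),
            key=lambda p: natural_key(p.name),
        )
        if not files:
            raise ShadingError(f"no images matching {pattern!r} in {path}")
        frames = [_read_frame(p) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise DimensionError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        dtype = frames[0].dtype
        return ImageStack(np.stack(frames), is_timelapse=is_timelapse,
                          pixel_dtype=dtype)
    if not path.exists():
        raise ShadingError(f"no such file: {path}")
    arr = _read_frame(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DimensionError(
            f"{path}: expected 2-D frames or a 3-D stack, got shape {arr.shape}"
        )
    return ImageStack(arr, is_timelapse=is_timelapse, pixel_dtype=arr.dtype)


def write_image_stack(stack: ImageStack, path, dtype="float32", clip: bool = False):
    """Write a stack as a multi-page TIFF.

    Output defaults to float32 — corrected intensities are ratios and do
    not fit integer semantics.  For integer dtypes, values are rounded
    and range-clipped; ``clip`` additionally floors negatives at 0 for
    float output.
    """
    path = Path(path)
    data = stack.frames
    dt = np.dtype(dtype)
    if clip:
        data = np.maximum(data, 0.0)
    if dt.kind in "ui":
        info = np.iinfo(dt)
        data = np.clip(np.rint(data), info.min, info.max)
    tifffile.imwrite(path, data.astype(dt), photometric="minisblack")
    return path


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_shading_model(model: ShadingModel, path, extra_metadata: dict | None = None):
    """Store a model as a 2-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    pages = np.stack([model.flatfield, model.darkfield]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "format": "shadecorr-shading-model",
        "version": __version__,
        "pages": ["flatfield", "darkfield"],
        "working_size": model.working_size,
        "shape": list(model.shape),
    }
    meta.update(model.metadata)
    if extra_metadata:
        meta.update(extra_metadata)
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path


def read_shading_model(path) -> ShadingModel:
    """Load a model and re-validate its invariants (S > 0, mean 1)."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ModelValidityError(
            f"{path}: expected 2 pages (flat-field, dark-field), "
            f"got shape {pages.shape}"
        )
    flat = pages[0].astype(np.float64)
    dark = pages[1].astype(np.float64)
    if np.any(flat <= 0):
        raise ModelValidityError(f"{path}: flat-field has non-positive values")
    m = flat.mean()
    if abs(m - 1.0) > 1e-3:  # float32 storage tolerance
        raise ModelValidityError(f"{path}: flat-field mean {m:.6g} is not 1")
    flat = flat / m
    meta = {}
    working_size = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        working_size = meta.get("working_size")
    return ShadingModel(flat, dark, working_size=working_size, metadata=meta)


def write_baselines(series: BaselineSeries, path):
    """Per-frame baseline table as JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "format": "shadecorr-baselines",
                "version": __version__,
                "b_norm": series.b_norm,
                "values": [float(v) for v in series.values],
            },
            fh, indent=2,
        )
        fh.write("\n")
    return path


def read_baselines(path) -> BaselineSeries:
    with open(path) as fh:
        payload = json.load(fh)
    return BaselineSeries(np.asarray(payload["values"], dtype=float),
                          b_norm=payload.get("b_norm", 0.0))
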