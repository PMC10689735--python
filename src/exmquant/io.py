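"""Shared I/O: TIFF images, CSV tables, JSON reports. All writes are atomic
(temp file in the destination directory, then rename)."""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "write_report",
    "max_project",
]


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in nm from TIFF resolution tags, if present and sane."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        pixels_per_unit = num / den
        unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", None) and int(unit.value))
        if unit_nm is None:
            return None
        return unit_nm / pixels_per_unit
    except Exception:
        return None


def read_image(path, pixel_size_nm: float | None = None) -> tuple[np.ndarray, float]:
    """Read a single- or multi-page TIFF; return (array, pixel size in nm).

    The pixel size is load-bearing for every downstream nm measurement: if it
    is neither given nor recoverable from the TIFF resolution tags this is a
    hard error. An explicit value overrides the tags (with a warning when
    they disagree).
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if pixel_size_nm is None:
        if tag_px is None:
            raise ValueError(
                f"{path}: pixel size missing; pass pixel_size_nm explicitly "
                "(nm units are load-bearing)"
            )
        pixel_size_nm = tag_px
    elif tag_px is not None and not np.isclose(tag_px, pixel_size_nm, rtol=0.01):
        warnings.warn(
            f"{path}: config pixel size {pixel_size_nm} nm overrides TIFF tag "
            f"{tag_px:.3g} nm"
        )
    return data, float(pixel_size_nm)


def write_image(path, image: np.ndarray, dtype=np.float32) -> None:
    """Write a TIFF atomically (float32 by default, lossless round-trip)."""
    arr = np.asarray(image).astype(dtype)
    _atomic_write(Path(path), lambda tmp: tifffile.imwrite(tmp, arr))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(records, path) -> None:
    """Write records (DataFrame or list of dicts) as CSV, atomically."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, index=False))


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path) -> None:
    """Write a JSON report atomically with stable key order."""
    _atomic_write(
        Path(path),
        lambda tmp: Path(tmp).write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
        ),
    )


def max_project(stack: np.ndarray) -> np.ndarray:
    """Max Z-projection of a (z, y, x) stack; 2D input passes through."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError(f"expected a 2D image or 3D stack, got shape {stack.shape}")
    return stack.max(axis=0)
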