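"""Readers, writers and run configuration.

Conventions used by every table and image in the package: coordinates are
0-based (z, y, x); ROI bounds are half-open; intensities are floating point
in memory regardless of on-disk bit depth; TIFF stacks are grayscale with
page order = z.  Every CSV/TSV written here starts with a ``#`` comment
header naming the tool version and the units of its columns, and readers
skip those comments.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_table",
    "read_table",
    "read_config",
    "write_resolved_config",
]


def read_image_stack(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF as a float (z, y, x) stack.

    Single-page files come back with shape (1, y, x).  RGB pages or pages of
    mismatched shape are a format error.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ValueError(f"{path}: RGB images are not supported")
    return arr.astype(float)


def write_image_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a float stack as 16-bit grayscale TIFF (page order = z).

    Intensities are clipped to [0, 65535] and rounded; this is the only
    place quantization happens.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    quantized = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), quantized)


def write_table(df: pd.DataFrame, path: str | Path, units: str,
                sep: str = ",") -> None:
    """Write a table with a comment header naming units and tool version."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# condquant v{__version__}\n")
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def read_config(path: str | Path, spec_type: type) -> Any:
    """Load a YAML mapping into a spec dataclass; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(spec_type)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    for key in ("image_shape", "center_xy", "radius_range_px", "background"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return spec_type(**raw)


def write_resolved_config(params: dict, path: str | Path) -> None:
    """Record the fully-resolved parameters of a run next to its outputs."""
    payload = {"tool": "condquant", "version": __version__, "params": params}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
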