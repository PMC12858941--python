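"""Quantized multi-band trait raster bundles.

A finished trait map ships as one multi-band TIFF holding the prediction,
its coefficient of variation, and the area-of-applicability mask, with a
JSON sidecar describing the grid, the per-band affine quantization
(``value ~ code * scale + offset``) and provenance metadata.  Continuous
bands are quantized to signed 16-bit integers — a factor-four size
reduction at a worst-case error of half a quantization step — while the
AOA band is stored losslessly as 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .grids import GridSpec

__all__ = ["TraitMapBundle", "write_trait_raster", "read_trait_raster"]

NODATA_CODE = np.int16(-32768)
_MAX_CODE = 32767  # symmetric code range; 2^16 - 2 usable steps


@dataclass
class TraitMapBundle:
    """Aligned map bands for one trait map plus metadata.

    ``bands`` maps band name to a float array of ``grid.shape``; NaN is
    nodata.  Boolean bands (the AOA mask) are stored exactly.
    """

    grid: GridSpec
    bands: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"band {name!r} shape mismatch")


def _quantize(arr: np.ndarray) -> tuple[np.ndarray, float, float]:
    valid = np.isfinite(arr)
    codes = np.full(arr.shape, NODATA_CODE, dtype=np.int16)
    if not valid.any():
        return codes, 1.0, 0.0
    lo, hi = float(arr[valid].min()), float(arr[valid].max())
    if hi == lo:  # constant band: offset-only encoding
        codes[valid] = 0
        return codes, 0.0, lo
    scale = (hi - lo) / (2**16 - 2)
    offset = (hi + lo) / 2.0
    q = np.round((arr[valid] - offset) / scale)
    codes[valid] = np.clip(q, -_MAX_CODE, _MAX_CODE).astype(np.int16)
    return codes, scale, offset


def write_trait_raster(bundle: TraitMapBundle, path: str | Path) -> None:
    """Write the bundle as an int16 multi-band TIFF with a JSON sidecar."""
    path = Path(path)
    names = list(bundle.bands)
    planes = []
    band_meta = []
    for name in names:
        arr = bundle.bands[name]
        if arr.dtype == bool:
            codes = arr.astype(np.int16)
            scale, offset, lossless = 1.0, 0.0, True
        else:
            codes, scale, offset = _quantize(np.asarray(arr, dtype=float))
            lossless = scale == 0.0
        planes.append(codes)
        band_meta.append(
            {"name": name, "scale": scale, "offset": offset,
             "boolean": bool(arr.dtype == bool), "lossless": lossless}
        )
    tifffile.imwrite(path, np.stack(planes), photometric="minisblack")
    sidecar = {
        "grid": bundle.grid.to_dict(),
        "nodata_code": int(NODATA_CODE),
        "bands": band_meta,
        "metadata": bundle.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_trait_raster(path: str | Path) -> TraitMapBundle:
    """Read a bundle written by :func:`write_trait_raster`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    grid = GridSpec.from_dict(sidecar["grid"])
    bands: dict[str, np.ndarray] = {}
    for plane, meta in zip(stack, sidecar["bands"]):
        if meta["boolean"]:
            bands[meta["name"]] = plane.astype(bool)
            continue
        arr = np.full(plane.shape, np.nan)
        valid = plane != sidecar["nodata_code"]
        arr[valid] = plane[valid] * meta["scale"] + meta["offset"]
        bands[meta["name"]] = arr
    return TraitMapBundle(grid=grid, bands=bands, metadata=sidecar.get("metadata", {}))
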