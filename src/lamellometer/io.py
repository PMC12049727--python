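"""Shared containers and TIFF/sidecar I/O.

Thickness maps are written as two-page TIFF files (float32 values in nm,
uint8 validity mask) with a JSON sidecar holding pixel size, method and
parameter provenance.  Image coordinates are row-major with the origin at
the top left; the physical y axis (lamella length) runs along rows.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError

VALID_METHODS = ("geometric", "tfi", "q4stem", "eftem", "synthetic")


@dataclass
class ThicknessMap:
    """2D lamella thickness field in nanometres.

    Parameters
    ----------
    values_nm:
        Thickness per pixel.  Invalid pixels may be NaN but must then be
        marked invalid in ``mask``.
    pixel_size_um:
        Physical pixel size, micrometres.
    method:
        Provenance of the estimate, one of ``geometric``, ``tfi``,
        ``q4stem``, ``eftem`` or ``synthetic``.
    mask:
        Boolean validity field, same shape as ``values_nm``.  ``None``
        means all pixels valid.
    metadata:
        Free-form parameter provenance (seeds, fit settings, ...).
    """

    values_nm: np.ndarray
    pixel_size_um: float
    method: str = "synthetic"
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if self.values_nm.ndim != 2:
            raise ValueError("values_nm must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.mask is None:
            self.mask = np.ones(self.values_nm.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values_nm.shape:
                raise ValueError("mask/shape mismatch")
        valid = self.values_nm[self.mask]
        if valid.size and np.nanmin(valid) < 0:
            raise ValueError("negative thickness inside valid mask")


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> Path:
    """Write ``tmap`` to a 2-page TIFF plus a JSON sidecar; returns the path."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        tw.write(tmap.values_nm.astype(np.float32))
        tw.write(tmap.mask.astype(np.uint8))
    sidecar = {
        "pixel_size_um": tmap.pixel_size_um,
        "method": tmap.method,
        "metadata": tmap.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_thickness_map(path: str | Path) -> ThicknessMap:
    """Read a map written by :func:`write_thickness_map`.

    A corrupted or missing sidecar degrades to a provenance warning; the
    thickness values themselves still load.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.pages[0].asarray().astype(float)
        mask = tif.pages[1].asarray().astype(bool) if len(tif.pages) > 1 else None
    sidecar_path = path.with_suffix(path.suffix + ".json")
    pixel_size, method, metadata = 1.0, "synthetic", {}
    try:
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = float(sidecar["pixel_size_um"])
        method = sidecar["method"]
        metadata = sidecar.get("metadata", {})
    except (OSError, KeyError, ValueError, json.JSONDecodeError):
        warnings.warn(
            f"missing or corrupt sidecar for {path.name}; provenance unknown",
            stacklevel=2,
        )
    return ThicknessMap(values, pixel_size, method=method, mask=mask, metadata=metadata)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in μm from OME-XML or TIFF resolution tags, if present."""
    if tif.ome_metadata:
        import re

        m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tif.ome_metadata)
        if m:
            return float(m.group(1))
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is not None and unit is not None:
        num, den = tag.value
        if num:
            per_unit = num / den
            # ResolutionUnit: 2 = inch, 3 = cm
            scale = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
            if scale and per_unit > 0:
                return scale / per_unit
    return None


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    timestamps_s: np.ndarray | None = None,
):
    """Read a single- or multi-page (OME-)TIFF stack.

    Returns ``(frames, pixel_size_um, timestamps_s)`` where ``frames`` has
    shape (n, y, x).  Pixel size comes from OME metadata or resolution
    tags; without either an explicit override is required.  Timestamps
    default to the OME plane DeltaT entries when present, else frame index.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
        ome = tif.ome_metadata
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"expected a 2D image stack, got shape {frames.shape}")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise FormatError(
            "no pixel size in metadata; pass pixel_size_um explicitly"
        )
    if timestamps_s is None:
        ts = None
        if ome:
            import re

            vals = re.findall(r'DeltaT="([0-9.eE+-]+)"', ome)
            if len(vals) == len(frames):
                ts = np.array([float(v) for v in vals])
        if ts is None:
            ts = np.arange(len(frames), dtype=float)
        timestamps_s = ts
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if len(timestamps_s) != len(frames):
        raise FormatError("timestamp count does not match frame count")
    return frames.astype(float), float(px), timestamps_s


def write_stack(
    path: str | Path,
    frames: np.ndarray,
    pixel_size_um: float,
    timestamps_s: np.ndarray | None = None,
) -> Path:
    """Write an OME-TIFF stack with pixel size and per-plane timestamps."""
    path = Path(path)
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {
        "axes": "TYX",
        "PhysicalSizeX": pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    if timestamps_s is not None:
        meta["Plane"] = {"DeltaT": [float(t) for t in timestamps_s]}
    tifffile.imwrite(path, frames, metadata=meta)
    return path
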