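"""Calibrated image containers and TIFF/CSV I/O.

Every measurement downstream is reported in physical units, so intensity
arrays are always carried together with their pixel calibration.  Images are
2D single-channel; stacks are ordered lists of planes sharing one in-plane
calibration plus a z-step and a height offset of the first plane above the
coverslip.

Conventions
-----------
* Arrays are row-major; pixel ``(r, c)`` has its centre at the physical
  position ``(x, y) = (c * pixel_size, r * pixel_size)``, i.e. positions are
  measured from pixel centres with the first pixel centre at the origin.
* Plane height ``= z0_offset + plane_index * z_step``; "surface" is height 0.
* All calibrations are stored in nanometres; reported distances use nm or µm
  as stated per field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, ImageFormatError

__all__ = [
    "CalibratedImage",
    "CalibratedStack",
    "read_image",
    "read_stack",
    "write_image",
    "write_stack",
    "write_results",
]


@dataclass
class CalibratedImage:
    """A 2D intensity image with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities.
    pixel_size_nm : float
        Edge length of a (square) pixel in nanometres.
    channel_label : str
        Free-text channel description (e.g. ``"F-actin"``).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ImageFormatError(
                f"image must be 2D with >= 2 rows and columns, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageFormatError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise ImageFormatError("image intensities must be non-negative")
        if not (self.pixel_size_nm > 0):
            raise CalibrationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Physical (height, width) of the field in µm."""
        return (
            self.shape[0] * self.pixel_size_um,
            self.shape[1] * self.pixel_size_um,
        )


@dataclass
class CalibratedStack:
    """An ordered z-stack of :class:`CalibratedImage` planes.

    ``z_step_nm`` is the spacing between consecutive planes and
    ``z0_offset_nm`` the height of the first plane above the coverslip;
    plane order is ascending height.
    """

    planes: list[CalibratedImage]
    z_step_nm: float
    z0_offset_nm: float = 0.0

    def __post_init__(self) -> None:
        if not self.planes:
            raise ImageFormatError("stack must contain at least one plane")
        shape0 = self.planes[0].shape
        ps0 = self.planes[0].pixel_size_nm
        for p in self.planes:
            if p.shape != shape0:
                raise ImageFormatError(
                    f"heterogeneous plane shapes in stack: {p.shape} != {shape0}"
                )
            if p.pixel_size_nm != ps0:
                raise ImageFormatError("planes disagree on pixel size")
        if not (self.z_step_nm > 0):
            raise CalibrationError(f"z_step_nm must be > 0, got {self.z_step_nm}")

    @property
    def pixel_size_nm(self) -> float:
        return self.planes[0].pixel_size_nm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.planes), *self.planes[0].shape)

    @property
    def plane_heights_nm(self) -> np.ndarray:
        """Height of each plane above the surface, in nm."""
        return self.z0_offset_nm + np.arange(len(self.planes)) * self.z_step_nm

    def as_array(self) -> np.ndarray:
        """Stack intensities as a (z, y, x) array."""
        return np.stack([p.pixels for p in self.planes])

    def crop_height(self, cap_nm: float) -> "CalibratedStack":
        """Return a stack restricted to planes with height <= ``cap_nm``."""
        keep = [p for p, h in zip(self.planes, self.plane_heights_nm) if h <= cap_nm]
        if not keep:
            keep = self.planes[:1]
        return CalibratedStack(keep, self.z_step_nm, self.z0_offset_nm)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Best-effort pixel size (nm) from TIFF metadata.

    Checks, in order: shaped (JSON) metadata written by this package, OME
    physical size, ImageJ metadata, and the X-resolution tag.
    """
    meta = tif.shaped_metadata
    if meta:
        for m in meta:
            if isinstance(m, dict) and "pixel_size_nm" in m:
                return float(m["pixel_size_nm"])
    if tif.ome_metadata:
        import re

        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
        if m:
            unit = re.search(r'PhysicalSizeXUnit="([^"]+)"', tif.ome_metadata)
            scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0}.get(
                unit.group(1) if unit else "µm", 1000.0
            )
            return float(m.group(1)) * scale
    ij = tif.imagej_metadata
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    if res is not None:
        num, den = res.value
        if num:
            # pixels per unit -> unit per pixel
            unit_tag = page.tags.get("ResolutionUnit")
            unit = getattr(unit_tag, "value", None)
            per_px = den / num
            if unit == 3:  # centimetre
                return per_px * 1e7
            if ij and ij.get("unit") in ("micron", "um", "µm"):
                return per_px * 1000.0
    return None


def read_image(
    path: str | Path,
    pixel_size_override_nm: float | None = None,
    plane: int | None = None,
    channel_label: str = "",
) -> CalibratedImage:
    """Read a single-plane TIFF as a :class:`CalibratedImage`.

    Calibration is taken from file metadata when present, else from
    ``pixel_size_override_nm``; if neither is available a
    :class:`~actinmesh.errors.CalibrationError` names the missing field.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_ps = _pixel_size_from_tiff(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ImageFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if data.ndim == 3:
        if plane is None:
            if data.shape[0] != 1:
                raise ImageFormatError(
                    f"{path} has {data.shape[0]} planes; pass `plane` to select one"
                )
            plane = 0
        data = data[plane]
    pixel_size = meta_ps if meta_ps is not None else pixel_size_override_nm
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel_size_nm in TIFF metadata and no override given"
        )
    return CalibratedImage(np.asarray(data, dtype=float), pixel_size, channel_label)


def read_stack(
    path: str | Path,
    pixel_size_override_nm: float | None = None,
    z_step_override_nm: float | None = None,
    z0_offset_nm: float = 0.0,
    height_cap_nm: float | None = 1000.0,
    channel_label: str = "",
) -> CalibratedStack:
    """Read a multi-plane TIFF as a :class:`CalibratedStack`.

    By default the stack is limited to planes within the first 1.0 µm above
    the surface (``height_cap_nm=1000``); pass ``None`` to keep all planes.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_ps = _pixel_size_from_tiff(tif)
            meta = tif.shaped_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ImageFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ImageFormatError(f"{path}: expected a 2D/3D TIFF, got shape {data.shape}")
    pixel_size = meta_ps if meta_ps is not None else pixel_size_override_nm
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel_size_nm in TIFF metadata and no override given"
        )
    z_step = None
    if meta:
        for m in meta:
            if isinstance(m, dict) and "z_step_nm" in m:
                z_step = float(m["z_step_nm"])
    if z_step is None:
        z_step = z_step_override_nm
    if z_step is None:
        raise CalibrationError(
            f"{path}: no z_step_nm in TIFF metadata and no override given"
        )
    planes = [
        CalibratedImage(np.asarray(p, dtype=float), pixel_size, channel_label)
        for p in data
    ]
    stack = CalibratedStack(planes, z_step, z0_offset_nm)
    if height_cap_nm is not None:
        stack = stack.crop_height(height_cap_nm)
    return stack


def write_image(path: str | Path, img: CalibratedImage) -> None:
    """Write a :class:`CalibratedImage` to TIFF with embedded calibration."""
    tifffile.imwrite(
        str(path),
        img.pixels.astype(np.float32),
        metadata={"pixel_size_nm": img.pixel_size_nm, "channel_label": img.channel_label},
    )


def write_stack(path: str | Path, stack: CalibratedStack) -> None:
    """Write a :class:`CalibratedStack` to a multi-page TIFF."""
    tifffile.imwrite(
        str(path),
        stack.as_array().astype(np.float32),
        photometric="minisblack",
        metadata={
            "pixel_size_nm": stack.pixel_size_nm,
            "z_step_nm": stack.z_step_nm,
            "z0_offset_nm": stack.z0_offset_nm,
        },
    )


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: dict[str, pd.DataFrame],
    images: dict[str, np.ndarray],
    outdir: str | Path,
    stage: str = "pipeline",
    config=None,
) -> dict:
    """Write tables (CSV), images (TIFF/PNG) and a JSON manifest.

    Label/float images are written as TIFF; RGB (H, W, 3) uint8 images as
    PNG.  The manifest lists every file with the producing stage and a hash
    of the configuration; it is returned and also written to
    ``manifest.json``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ImageFormatError(f"cannot create output directory {outdir}: {exc}") from exc
    entries = []
    for name, df in tables.items():
        fn = outdir / f"{name}.csv"
        df.to_csv(fn, index=False, lineterminator="\n")
        entries.append({"file": fn.name, "kind": "table", "rows": int(len(df)), "stage": stage})
    for name, arr in images.items():
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] in (3, 4) and arr.dtype == np.uint8:
            import imageio.v3 as iio

            fn = outdir / f"{name}.png"
            iio.imwrite(fn, arr)
        else:
            fn = outdir / f"{name}.tiff"
            tifffile.imwrite(str(fn), arr)
        entries.append({"file": fn.name, "kind": "image", "stage": stage})
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config) if config is not None else None,
        "files": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
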