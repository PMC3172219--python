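"""Segmentation of cortical actin and parameterisation of mesh "holes".

A hole is a connected component (8-connectivity) of actin-negative pixels
within the central synapse region.  Filaments use the complementary
4-connectivity so that foreground and background tilings are topologically
consistent.  Components below the microscope resolution floor (default
0.01 µm²) are discarded.  The summary "width" of the mesh is the side of
the square with the mean hole area, sqrt(mean area) — the convention that
maps a 0.2 µm² mean hole to a ~450 nm gap and 0.04 µm² to 200 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .errors import DegenerateThresholdError, UndefinedStatisticError
from .geometry import CentralRegion
from .images import CalibratedImage

__all__ = [
    "ActinMask",
    "HoleTable",
    "segment_actin",
    "extract_holes",
    "mean_hole_width",
    "hole_heatmap",
]

#: 8-connectivity structuring element for hole labelling.
_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class ActinMask:
    """Binary actin segmentation: True = actin-positive ("filament") pixel."""

    mask: np.ndarray
    pixel_size_nm: float
    method: str = "passthrough"
    threshold: float | None = None


@dataclass
class HoleTable:
    """Per-hole measurements plus summary statistics.

    ``table`` has one row per retained hole: id, pixel count, area (µm²),
    centroid (µm), and whether the hole touches the central-region border.
    ``labels`` is the full-frame hole label image (0 = not a retained hole).
    """

    table: pd.DataFrame
    labels: np.ndarray
    pixel_size_nm: float
    region_area_um2: float

    @property
    def n_holes(self) -> int:
        return len(self.table)

    @property
    def mean_area_um2(self) -> float:
        if self.n_holes == 0:
            return float("nan")
        return float(self.table["area_um2"].mean())

    @property
    def mean_width_nm(self) -> float:
        if self.n_holes == 0:
            return float("nan")
        return mean_hole_width(self)


def segment_actin(
    img: CalibratedImage,
    method: str = "otsu",
    param: float | None = None,
    region: CentralRegion | None = None,
) -> ActinMask:
    """Threshold an actin image into filament (True) / hole (False) pixels.

    Binary input (values ⊆ {0, 1}) passes through unchanged regardless of
    method.  ``otsu`` computes the threshold within ``region`` when given
    (the bright peripheral ring would skew a global threshold), ``percentile``
    thresholds at the given in-region percentile, ``fixed`` at ``param``.
    """
    pixels = img.pixels
    vals = np.unique(pixels)
    if len(vals) <= 2 and set(vals).issubset({0.0, 1.0}):
        return ActinMask(pixels > 0.5, img.pixel_size_nm, "passthrough", 0.5)
    sample = pixels[region.mask] if region is not None else pixels
    if method == "otsu":
        if sample.max() == sample.min():
            raise DegenerateThresholdError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(sample))
    elif method == "percentile":
        if param is None:
            raise ValueError("percentile method requires param in (0, 100)")
        thr = float(np.percentile(sample, param))
    elif method == "fixed":
        if param is None:
            raise ValueError("fixed method requires a threshold param")
        thr = float(param)
    elif method == "halfmax":
        thr = float(sample.min() + 0.5 * (sample.max() - sample.min()))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return ActinMask(pixels >= thr, img.pixel_size_nm, method, thr)


def extract_holes(
    actin: ActinMask,
    region: CentralRegion,
    min_area_um2: float = 0.01,
    exclude_border_touching: bool = False,
) -> HoleTable:
    """Extract mesh holes within the central region.

    Holes are 8-connected components of actin-negative pixels intersected
    with the region mask; components smaller than ``min_area_um2`` are
    discarded (resolution floor).  Holes touching the region border are
    flagged and, optionally, excluded.  An image with no holes yields an
    empty table, not an error.
    """
    if not region.mask.any():
        raise UndefinedStatisticError("empty central region")
    px_um = actin.pixel_size_nm / 1000.0
    px_area = px_um**2
    holes = (~actin.mask) & region.mask
    labels, n = ndimage.label(holes, structure=_STRUCT8)
    border = region.mask & ~ndimage.binary_erosion(
        region.mask, structure=_STRUCT8, border_value=0
    )
    rows = []
    keep = np.zeros(n + 1, dtype=bool)
    if n:
        border_labels = set(np.unique(labels[border])) - {0}
        for prop in regionprops(labels):
            area = prop.area * px_area
            if area < min_area_um2:
                continue
            touches = prop.label in border_labels
            if exclude_border_touching and touches:
                continue
            keep[prop.label] = True
            cy, cx = prop.centroid
            rows.append(
                {
                    "hole": prop.label,
                    "n_pixels": int(prop.area),
                    "area_um2": area,
                    "x_um": cx * px_um,
                    "y_um": cy * px_um,
                    "touches_central_border": touches,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["hole", "n_pixels", "area_um2", "x_um", "y_um",
                 "touches_central_border"],
    )
    labels_out = np.where(keep[labels], labels, 0)
    return HoleTable(table, labels_out, actin.pixel_size_nm, region.area_um2)


def mean_hole_width(holes: HoleTable) -> float:
    """Square-equivalent mean gap width in nm: sqrt(mean hole area).

    Raises :class:`UndefinedStatisticError` for an empty table.
    """
    if holes.n_holes == 0:
        raise UndefinedStatisticError("mean width undefined for 0 holes")
    return float(np.sqrt(holes.table["area_um2"].mean())) * 1000.0


def hole_heatmap(
    holes: HoleTable,
    actin: ActinMask,
    bounds_um2: tuple[float, float] = (0.01, 3.0),
) -> np.ndarray:
    """False-colour heat map of hole areas (RGB uint8).

    Each hole's pixels are coloured by hole area on a blue→red scale clipped
    to ``bounds_um2`` (defaults: 0.01 µm², the resolution limit, at the blue
    end; areas above 3.0 µm² clipped to red).  Filament pixels are neutral
    grey.
    """
    from matplotlib import colormaps

    lo, hi = bounds_um2
    cmap = colormaps["jet"]
    rgb = np.full((*actin.mask.shape, 3), 40, dtype=np.uint8)
    rgb[actin.mask] = 90
    if holes.n_holes:
        # log scaling spreads the two decades between floor and clip
        log_lo, log_hi = np.log10(lo), np.log10(hi)
        for _, row in holes.table.iterrows():
            frac = (np.log10(max(row["area_um2"], lo)) - log_lo) / (log_hi - log_lo)
            colour = (np.array(cmap(float(np.clip(frac, 0, 1)))[:3]) * 255).astype(np.uint8)
            rgb[holes.labels == row["hole"]] = colour
    return rgb
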