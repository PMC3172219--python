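"""Distance-to-actin fields and granule-penetrability maps.

The distance map assigns every actin-negative ("hole") pixel its Euclidean
distance to the nearest actin-positive ("filament") pixel, zero on filament
pixels.  Thresholding by the granule radius yields the region a rigid
spherical granule could traverse without deforming.

Threshold semantics
-------------------
``distance_map`` reports pixel-centre to pixel-centre distances (the corner
pixel of a 5×5 grid with one central positive pixel is at 2√2 px).  The
penetrability test, however, asks whether a granule centred on a hole pixel
clears the actin *material*, which begins at the near edge of the nearest
filament pixel — half a pixel closer than that pixel's centre.  A pixel is
therefore penetrable iff

    (EDT − ½ px) ≥ granule radius        (">=", not ">")

computed in exact integer-squared arithmetic so that pixel-aligned fixtures
are pixel-exact: for a square hole of side s and granule radius ρ, both
integer multiples of the pixel size, the penetrable region is exactly the
inner square of side s − 2ρ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import UndefinedStatisticError
from .geometry import CentralRegion
from .holes import ActinMask

__all__ = [
    "DistanceMap",
    "PenetrableMask",
    "PenetrableDomain",
    "distance_map",
    "penetrable_mask",
    "penetrable_fraction_curve",
    "penetrable_domains",
]


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (µm) to the nearest actin pixel."""

    values_um: np.ndarray
    pixel_size_nm: float
    #: exact squared pixel-centre distances (integers), for exact thresholding
    sq_px: np.ndarray = None

    @property
    def values_px(self) -> np.ndarray:
        return self.values_um * 1000.0 / self.pixel_size_nm


@dataclass
class PenetrableMask:
    """Binary map of pixels a granule of the given diameter can occupy."""

    mask: np.ndarray
    granule_diameter_nm: float
    fraction_pct: float
    region: CentralRegion


@dataclass
class PenetrableDomain:
    """A connected penetrable cluster with its admitted diameter band."""

    domain_id: int
    band_nm: float
    area_um2: float
    centroid_um: tuple[float, float]
    distance_from_centre_um: float


def distance_map(actin: ActinMask) -> DistanceMap:
    """Exact Euclidean distance transform of the hole set, in µm.

    Raises :class:`UndefinedStatisticError` when there is no actin-positive
    pixel (every distance would be infinite).
    """
    if not actin.mask.any():
        raise UndefinedStatisticError("no actin-positive pixel: distances undefined")
    edt_px = ndimage.distance_transform_edt(~actin.mask)
    # squared centre-to-centre distances are integers; recover them exactly
    sq_px = np.rint(edt_px**2).astype(np.int64)
    return DistanceMap(edt_px * actin.pixel_size_nm / 1000.0, actin.pixel_size_nm, sq_px)


def _penetrable(dist: DistanceMap, granule_diameter_nm: float) -> np.ndarray:
    """Boundary-clearance >= radius, via exact integer-squared comparison."""
    rho_px = (granule_diameter_nm / 2.0) / dist.pixel_size_nm
    thr = rho_px + 0.5  # clearance >= rho  <=>  centre distance >= rho + 1/2
    if dist.sq_px is not None:
        return dist.sq_px >= thr**2
    return dist.values_px >= thr


def penetrable_mask(
    dist: DistanceMap,
    granule_diameter_nm: float,
    region: CentralRegion,
) -> PenetrableMask:
    """Threshold the distance map by the granule radius.

    ``fraction_pct`` is the percentage of central-region pixels that are
    penetrable.
    """
    if granule_diameter_nm <= 0:
        raise ValueError("granule diameter must be > 0")
    pen = _penetrable(dist, granule_diameter_nm)
    n_region = region.n_pixels
    frac = 100.0 * float((pen & region.mask).sum()) / n_region if n_region else 0.0
    return PenetrableMask(pen, granule_diameter_nm, frac, region)


def penetrable_fraction_curve(
    dist: DistanceMap,
    region: CentralRegion,
    diameters_nm,
) -> pd.DataFrame:
    """Penetrable fraction of the region for each granule diameter.

    The fraction is monotone non-increasing in diameter.
    """
    rows = [
        {
            "diameter_nm": float(d),
            "fraction_pct": penetrable_mask(dist, d, region).fraction_pct,
        }
        for d in diameters_nm
    ]
    return pd.DataFrame(rows)


def penetrable_domains(
    dist: DistanceMap,
    region: CentralRegion,
    bands_nm=(200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0),
) -> tuple[list[PenetrableDomain], pd.DataFrame, np.ndarray]:
    """Connected penetrable clusters, banded by the largest admitted granule.

    Domains are connected components (8-connectivity) of the mask for the
    smallest band diameter.  Each is labelled with the largest band whose
    granule its widest point admits (max clearance >= band radius, i.e. the
    largest inscribed disc), the paper-style blue (small) → red (large)
    banding.  Per-domain centroid distances from the synapse centre are
    reported alongside a banded RGB map.
    """
    bands = sorted(float(b) for b in bands_nm)
    px_um = dist.pixel_size_nm / 1000.0
    base = _penetrable(dist, bands[0]) & region.mask
    labels, n = ndimage.label(base, structure=np.ones((3, 3), int))
    cx0, cy0 = region.centre_um
    from matplotlib import colormaps

    cmap = colormaps["jet"]
    rgb = np.zeros((*base.shape, 3), dtype=np.uint8)
    domains: list[PenetrableDomain] = []
    rows = []
    for lab in range(1, n + 1):
        comp = labels == lab
        max_sq = dist.sq_px[comp].max() if dist.sq_px is not None else None
        admitted = bands[0]
        for b in bands:
            thr = (b / 2.0) / dist.pixel_size_nm + 0.5
            ok = (max_sq >= thr**2) if max_sq is not None else (
                dist.values_px[comp].max() >= thr
            )
            if ok:
                admitted = b
        com = ndimage.center_of_mass(comp)
        cx, cy = com[1] * px_um, com[0] * px_um
        d_centre = float(np.hypot(cx - cx0, cy - cy0))
        area = float(comp.sum()) * px_um**2
        domains.append(PenetrableDomain(lab, admitted, area, (cx, cy), d_centre))
        rows.append(
            {"domain": lab, "band_nm": admitted, "area_um2": area, "x_um": cx,
             "y_um": cy, "distance_from_centre_um": d_centre}
        )
        frac = (admitted - bands[0]) / (bands[-1] - bands[0]) if len(bands) > 1 else 1.0
        rgb[comp] = (np.array(cmap(frac)[:3]) * 255).astype(np.uint8)
    table = pd.DataFrame(
        rows, columns=["domain", "band_nm", "area_um2", "x_um", "y_um",
                       "distance_from_centre_um"]
    )
    return domains, table, rgb
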