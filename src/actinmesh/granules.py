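"""Granule detection, sizing, docking statistics and ring-relative stats.

Granules are detected in calibrated z-stacks as 3D local maxima and
localised by intensity-weighted centroids.  Diameters come from a 2D
Gaussian fit at the brightest plane with the microscope PSF removed in
quadrature, floored at the 100 nm resolution limit.  Docking statistics
relate granule positions to the penetrability map: height strata above the
surface, in-plane distances to the nearest penetrable pixel, and the odds
ratio of landing on a penetrable domain

    OR = [p / (1 - p)] / [f / (1 - f)]

where p is the fraction of granules in an axial bin whose lateral centroid
lies on a penetrable pixel and f the penetrable fraction of the central
region; OR ≈ 1 for uniformly scattered granules, > 1 for preferential
docking.  The MTOC is handled as the single-brightest-blob special case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .errors import DetectionError, FitError, UndefinedStatisticError
from .geometry import CentralRegion, RingGeometry
from .images import CalibratedImage, CalibratedStack
from .penetrability import PenetrableMask
from .synth import FWHM_TO_SIGMA

__all__ = [
    "RingRelativeStats",
    "detect_granules",
    "estimate_diameter",
    "height_strata",
    "lateral_distance_to_penetrable",
    "odds_ratio",
    "ring_relative_stats",
    "mtoc_position",
]

RESOLUTION_FLOOR_NM = 100.0


@dataclass
class RingRelativeStats:
    """Particle signal partitioned by the ring borders, plus radial profile."""

    inside_pct: float
    on_ring_pct: float
    outside_pct: float
    profile: pd.DataFrame  # radius_um, frequency_per_um2
    mean_radius_um: float


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (offset + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))).ravel()


def estimate_diameter(
    patch: np.ndarray,
    pixel_size_nm: float,
    psf_fwhm_nm: float = 100.0,
) -> float:
    """Granule diameter from a 2D Gaussian fit with quadrature PSF removal.

    ``diameter = sqrt(max(FWHM_fit² − psf_fwhm², 0))``, floored at the
    100 nm resolution limit.  Raises :class:`FitError` on non-convergence.
    """
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    y, x = np.mgrid[0:h, 0:w]
    lo = float(patch.min())
    amp0 = float(patch.max() - lo)
    if amp0 <= 0:
        raise FitError("flat patch: no spot to fit")
    cy, cx = np.unravel_index(np.argmax(patch), patch.shape)
    p0 = [amp0, float(cx), float(cy), max(psf_fwhm_nm * FWHM_TO_SIGMA / pixel_size_nm, 1.0), lo]
    try:
        popt, _ = curve_fit(_gauss2d, (x, y), patch.ravel(), p0=p0, maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"granule fit did not converge: {exc}") from exc
    fwhm_nm = abs(popt[3]) / FWHM_TO_SIGMA * pixel_size_nm
    d = math.sqrt(max(fwhm_nm**2 - psf_fwhm_nm**2, 0.0))
    return max(d, RESOLUTION_FLOOR_NM)


def detect_granules(
    stack: CalibratedStack,
    min_diameter_nm: float = 100.0,
    psf_fwhm_nm: float = 100.0,
    threshold_abs: float | None = None,
    min_separation_nm: float = 300.0,
    patch_half_px: int = 10,
) -> pd.DataFrame:
    """Detect granules in a z-stack and measure 3D centroids and diameters.

    Local maxima of the lightly smoothed stack above ``threshold_abs``
    (default: median + 8 robust SD) are localised by intensity-weighted 3D
    centroids; peaks closer than ``min_separation_nm`` in-plane merge into
    one detection (spots below the separation limit are not double-counted).
    Spots whose estimated diameter falls below ``min_diameter_nm`` are
    discarded; failed fits are flagged (``fit_ok=False``) and excluded from
    summaries by callers.

    Returns a DataFrame with columns granule, x_um, y_um, z_nm,
    diameter_nm, peak_intensity, fit_ok.
    """
    arr = stack.as_array()
    px_nm = stack.pixel_size_nm
    px_um = px_nm / 1000.0
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    if info is not None and (arr == info.max).all():
        raise DetectionError("stack is saturated everywhere")
    if arr.max() == arr.min():
        if arr.size and float(arr.max()) >= 65535:
            raise DetectionError("stack is saturated everywhere")
        return pd.DataFrame(
            columns=["granule", "x_um", "y_um", "z_nm", "diameter_nm",
                     "peak_intensity", "fit_ok"]
        )
    smooth = ndimage.gaussian_filter(arr, (0.5, 1.0, 1.0))
    if threshold_abs is None:
        med = float(np.median(smooth))
        mad = float(np.median(np.abs(smooth - med))) * 1.4826
        threshold_abs = med + 8.0 * max(mad, 1e-6)
    min_sep_px = max(int(round(min_separation_nm / px_nm)), 1)
    peaks = peak_local_max(
        smooth,
        min_distance=min_sep_px,
        threshold_abs=threshold_abs,
        exclude_border=False,
    )
    heights = stack.plane_heights_nm
    bg = float(np.median(arr))
    rows = []
    for i, (pz, pr, pc) in enumerate(peaks):
        r0, r1 = max(0, pr - patch_half_px), min(arr.shape[1], pr + patch_half_px + 1)
        c0, c1 = max(0, pc - patch_half_px), min(arr.shape[2], pc + patch_half_px + 1)
        sub = arr[:, r0:r1, c0:c1] - bg
        sub = np.clip(sub, 0, None)
        zz, yy, xx = np.mgrid[0 : arr.shape[0], r0:r1, c0:c1]
        w = sub.sum()
        if w <= 0:
            continue
        zc = float((sub * zz).sum() / w)
        yc = float((sub * yy).sum() / w)
        xc = float((sub * xx).sum() / w)
        z_nm = stack.z0_offset_nm + zc * stack.z_step_nm
        patch = arr[pz, r0:r1, c0:c1]
        try:
            d = estimate_diameter(patch, px_nm, psf_fwhm_nm)
            fit_ok = True
        except FitError:
            d, fit_ok = float("nan"), False
        if fit_ok and d < min_diameter_nm:
            continue
        rows.append(
            {
                "granule": i,
                "x_um": xc * px_um,
                "y_um": yc * px_um,
                "z_nm": z_nm,
                "diameter_nm": d,
                "peak_intensity": float(arr[pz, pr, pc]),
                "fit_ok": fit_ok,
            }
        )
    df = pd.DataFrame(
        rows, columns=["granule", "x_um", "y_um", "z_nm", "diameter_nm",
                       "peak_intensity", "fit_ok"]
    )
    df["granule"] = range(len(df))
    return df


def height_strata(
    granules: pd.DataFrame,
    edges_nm=(0.0, 250.0, 500.0, 750.0, 1000.0),
) -> pd.DataFrame:
    """Fraction of granules per height stratum above the surface.

    Strata are half-open ``[lower, upper)`` except the last, which is
    closed, so the fractions over strata covering the analysed depth sum to
    100%.  Raises on an empty table.
    """
    if len(granules) == 0:
        raise UndefinedStatisticError("height strata undefined for 0 granules")
    edges = np.asarray(edges_nm, dtype=float)
    counts, _ = np.histogram(granules["z_nm"].to_numpy(), bins=edges)
    frac = 100.0 * counts / len(granules)
    return pd.DataFrame(
        {
            "stratum_lo_nm": edges[:-1],
            "stratum_hi_nm": edges[1:],
            "count": counts,
            "fraction_pct": frac,
        }
    )


def _distance_to_mask_um(pen: PenetrableMask, pixel_size_nm: float) -> np.ndarray:
    """Per-pixel in-plane distance (µm) to the nearest penetrable pixel."""
    return ndimage.distance_transform_edt(~pen.mask) * pixel_size_nm / 1000.0


def lateral_distance_to_penetrable(
    granules: pd.DataFrame,
    pen: PenetrableMask,
    pixel_size_nm: float,
    strata_edges_nm=(0.0, 250.0, 500.0, 750.0, 1000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-plane distance of each granule to the nearest penetrable pixel.

    The axial coordinate is ignored: a granule 1 µm up still scores its x-y
    distance.  Returns the granule table with a ``lateral_distance_um``
    column (NaN + ``distance_defined=False`` when the penetrable mask is
    empty) and a per-stratum mean-distance summary.
    """
    out = granules.copy()
    if not pen.mask.any():
        out["lateral_distance_um"] = np.nan
        out["distance_defined"] = False
        summary = pd.DataFrame(
            columns=["stratum_lo_nm", "stratum_hi_nm", "mean_distance_um", "n"]
        )
        return out, summary
    dist = _distance_to_mask_um(pen, pixel_size_nm)
    px_um = pixel_size_nm / 1000.0
    rr = np.clip(np.rint(out["y_um"] / px_um).astype(int), 0, dist.shape[0] - 1)
    cc = np.clip(np.rint(out["x_um"] / px_um).astype(int), 0, dist.shape[1] - 1)
    out["lateral_distance_um"] = dist[rr, cc]
    out["distance_defined"] = True
    edges = np.asarray(strata_edges_nm, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (out["z_nm"] >= lo) & (
            (out["z_nm"] < hi) if hi < edges[-1] else (out["z_nm"] <= hi)
        )
        rows.append(
            {
                "stratum_lo_nm": lo,
                "stratum_hi_nm": hi,
                "mean_distance_um": float(out.loc[sel, "lateral_distance_um"].mean())
                if sel.any()
                else float("nan"),
                "n": int(sel.sum()),
            }
        )
    return out, pd.DataFrame(rows)


def odds_ratio(
    granules: pd.DataFrame,
    pen: PenetrableMask,
    region: CentralRegion,
    axial_edges_nm=tuple(np.arange(0.0, 1000.0, 100.0)),
) -> pd.DataFrame:
    """Odds ratio for granules to land on penetrable pixels, per axial bin.

    With f the penetrable fraction of the central region and p the fraction
    of a bin's granules whose lateral centroid lies on a penetrable pixel:
    ``OR = [p/(1-p)] / [f/(1-f)]``.  p = 0 gives OR 0, p = 1 gives +inf;
    bins with no granules report NaN (undefined, not zero).  f in {0, 1}
    raises, since the baseline odds are degenerate.
    """
    f = (pen.mask & region.mask).sum() / region.n_pixels
    if f <= 0.0 or f >= 1.0:
        raise UndefinedStatisticError(
            f"penetrable fraction f={f} gives degenerate baseline odds"
        )
    px_um = pen.region.pixel_size_nm / 1000.0
    edges = np.asarray(axial_edges_nm, dtype=float)
    base_odds = f / (1.0 - f)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = granules[(granules["z_nm"] >= lo) & (granules["z_nm"] < hi)]
        n = len(sel)
        if n == 0:
            rows.append({"bin_lo_nm": lo, "bin_hi_nm": hi, "n": 0,
                         "p_on_penetrable": np.nan, "odds_ratio": np.nan})
            continue
        rr = np.clip(np.rint(sel["y_um"] / px_um).astype(int), 0, pen.mask.shape[0] - 1)
        cc = np.clip(np.rint(sel["x_um"] / px_um).astype(int), 0, pen.mask.shape[1] - 1)
        p = float(pen.mask[rr, cc].mean())
        if p >= 1.0:
            orv = float("inf")
        elif p <= 0.0:
            orv = 0.0
        else:
            orv = (p / (1.0 - p)) / base_odds
        rows.append({"bin_lo_nm": lo, "bin_hi_nm": hi, "n": n,
                     "p_on_penetrable": p, "odds_ratio": orv})
    out = pd.DataFrame(rows)
    out.attrs["penetrable_fraction"] = f
    return out


def ring_relative_stats(
    particles: pd.DataFrame | CalibratedImage,
    ring: RingGeometry,
    pixel_size_nm: float | None = None,
    bin_width_um: float = 0.5,
    signal_threshold: float | None = None,
) -> RingRelativeStats:
    """Partition particle signal by the ring borders and profile it radially.

    ``particles`` is either a table with x_um/y_um columns (counts mode) or
    a calibrated intensity image, in which case thresholded signal pixels
    (default threshold: half-maximum) are used, weighted by intensity.
    Fractions inside the inner border / on the annulus / outside the outer
    border sum to 100% of in-field signal.  The radial profile divides each
    annular bin's signal by the bin area ("frequency normalised by area").
    """
    from .errors import NoRingError

    if not ring.has_ring:
        raise NoRingError("ring-relative statistics require a ring")
    cx, cy = ring.centroid_um
    if isinstance(particles, CalibratedImage):
        px_um = particles.pixel_size_um
        img = particles.pixels
        thr = (
            signal_threshold
            if signal_threshold is not None
            else img.min() + 0.5 * (img.max() - img.min())
        )
        rr, cc = np.indices(img.shape)
        sel = img >= thr
        radii = np.hypot(rr[sel] * px_um - cy, cc[sel] * px_um - cx)
        weights = img[sel].astype(float)
    else:
        if len(particles) == 0:
            raise UndefinedStatisticError("no particles")
        radii = np.hypot(
            particles["x_um"].to_numpy() - cx, particles["y_um"].to_numpy() - cy
        )
        weights = np.ones_like(radii)
    total = weights.sum()
    r_in = ring.inner_diameter_um / 2.0
    r_out = ring.outer_diameter_um / 2.0
    inside = 100.0 * weights[radii < r_in].sum() / total
    on_ring = 100.0 * weights[(radii >= r_in) & (radii <= r_out)].sum() / total
    outside = 100.0 * weights[radii > r_out].sum() / total
    r_max = max(radii.max(), r_out) + bin_width_um
    edges = np.arange(0.0, r_max + bin_width_um, bin_width_um)
    counts, _ = np.histogram(radii, bins=edges, weights=weights)
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    profile = pd.DataFrame(
        {
            "radius_um": 0.5 * (edges[:-1] + edges[1:]),
            "frequency_per_um2": counts / areas,
        }
    )
    mean_r = float((radii * weights).sum() / total)
    return RingRelativeStats(inside, on_ring, outside, profile, mean_r)


def mtoc_position(
    stack: CalibratedStack,
    pen: PenetrableMask | None = None,
    threshold_rel: float = 0.5,
) -> tuple[float, float]:
    """MTOC height above the surface (µm) and lateral distance to the
    nearest penetrable pixel (µm; NaN if no mask given).

    The MTOC is the intensity-weighted centroid of the brightest 3D blob
    (pixels above ``threshold_rel`` of the maximum, connected to it).
    Raises :class:`DetectionError` when no blob rises above background.
    """
    arr = stack.as_array()
    bg = float(np.median(arr))
    peak = float(arr.max())
    if peak <= bg:
        raise DetectionError("no MTOC blob above background")
    thr = bg + threshold_rel * (peak - bg)
    above = arr >= thr
    labels, n = ndimage.label(above)
    if n == 0:
        raise DetectionError("no MTOC blob above threshold")
    peak_idx = np.unravel_index(np.argmax(arr), arr.shape)
    blob = labels == labels[peak_idx]
    w = (arr - bg) * blob
    total = w.sum()
    zz, yy, xx = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1], 0 : arr.shape[2]]
    zc = float((w * zz).sum() / total)
    yc = float((w * yy).sum() / total)
    xc = float((w * xx).sum() / total)
    height_um = (stack.z0_offset_nm + zc * stack.z_step_nm) / 1000.0
    if pen is None:
        return height_um, float("nan")
    dist = _distance_to_mask_um(pen, stack.pixel_size_nm)
    r = int(np.clip(round(yc), 0, dist.shape[0] - 1))
    c = int(np.clip(round(xc), 0, dist.shape[1] - 1))
    return height_um, float(dist[r, c])
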