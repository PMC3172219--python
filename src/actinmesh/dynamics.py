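"""Microcluster tracking, Pearson colocalisation and Gaussian FWHM fits.

Tracking links per-frame spot detections by greedy nearest-neighbour
assignment with a maximum-step gate (default 1.5 µm per frame, comfortably
above the ~1 µm/s top speed of centripetal receptor microclusters imaged at
1 frame per second) and a one-frame gap tolerance.  Per-track summaries
include the mean speed (path length / duration), net displacement, and a
centripetal index: net displacement toward a supplied centre divided by
path length, +1 for a straight inward run.

FWHM fits decompose a 1D intensity profile into a sum of Gaussians plus a
constant baseline; each component reports FWHM = 2 sqrt(2 ln 2) sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .errors import FitError, UndefinedStatisticError
from .images import CalibratedImage
from .synth import FWHM_TO_SIGMA

__all__ = [
    "Track",
    "FWHMFit",
    "detect_clusters",
    "link_tracks",
    "pearson_colocalization",
    "fit_fwhm",
]


@dataclass
class Track:
    """One linked microcluster trajectory with summary kinematics."""

    track_id: int
    points: pd.DataFrame  # t_s, x_um, y_um
    mean_speed_um_s: float
    net_displacement_um: float
    centripetal_index: float  # in [-1, 1]; NaN when no centre supplied


@dataclass
class FWHMFit:
    """Multi-component Gaussian fit of a 1D profile."""

    components: pd.DataFrame  # amplitude, centre_nm, sigma_nm, fwhm_nm
    baseline: float
    residual_norm: float


def detect_clusters(
    frame: CalibratedImage,
    min_intensity: float | None = None,
    min_separation_um: float = 0.8,
    refine_half_px: int = 3,
) -> pd.DataFrame:
    """Detect bright clusters in one frame with sub-pixel centroids.

    Local maxima of the lightly smoothed frame above ``min_intensity``
    (default: median + 8 robust SD) are refined by intensity-weighted
    centroids in a small window.  Returns x_um, y_um, intensity; an empty
    frame yields an empty table.
    """
    img = frame.pixels
    px_um = frame.pixel_size_um
    smooth = ndimage.gaussian_filter(img, 1.0)
    if min_intensity is None:
        med = float(np.median(smooth))
        mad = float(np.median(np.abs(smooth - med))) * 1.4826
        min_intensity = med + 8.0 * max(mad, 1e-6)
    peaks = peak_local_max(
        smooth,
        min_distance=max(int(round(min_separation_um / px_um)), 1),
        threshold_abs=min_intensity,
        exclude_border=False,
    )
    bg = float(np.median(img))
    rows = []
    for pr, pc in peaks:
        r0, r1 = max(0, pr - refine_half_px), min(img.shape[0], pr + refine_half_px + 1)
        c0, c1 = max(0, pc - refine_half_px), min(img.shape[1], pc + refine_half_px + 1)
        sub = np.clip(img[r0:r1, c0:c1] - bg, 0, None)
        w = sub.sum()
        if w <= 0:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        rows.append(
            {
                "x_um": float((sub * xx).sum() / w) * px_um,
                "y_um": float((sub * yy).sum() / w) * px_um,
                "intensity": float(img[pr, pc]),
            }
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "intensity"])


def link_tracks(
    frame_spots: list[pd.DataFrame],
    frame_interval_s: float = 1.0,
    max_step_um: float = 1.5,
    centre_um: tuple[float, float] | None = None,
    max_gap: int = 1,
    min_length: int = 3,
) -> list[Track]:
    """Link per-frame detections into tracks by greedy nearest neighbour.

    At each frame, open track ends are matched to the closest new spot in
    ascending-distance order, gated at ``max_step_um`` per elapsed frame;
    tracks may skip up to ``max_gap`` frames.  Unmatched spots open new
    tracks; tracks shorter than ``min_length`` points are dropped.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame interval must be > 0")
    active: list[dict] = []
    done: list[dict] = []
    for f, spots in enumerate(frame_spots):
        pts = spots[["x_um", "y_um"]].to_numpy() if len(spots) else np.zeros((0, 2))
        # candidate (distance, track, spot) pairs within the gate
        pairs = []
        for ti, tr in enumerate(active):
            gap = f - tr["last_frame"]
            if gap > max_gap + 1:
                continue
            gate = max_step_um * gap
            last = tr["xy"][-1]
            for si in range(len(pts)):
                d = math.hypot(pts[si, 0] - last[0], pts[si, 1] - last[1])
                if d <= gate:
                    pairs.append((d, ti, si))
        pairs.sort(key=lambda p: p[0])
        used_t: set[int] = set()
        used_s: set[int] = set()
        for d, ti, si in pairs:
            if ti in used_t or si in used_s:
                continue
            tr = active[ti]
            tr["xy"].append((float(pts[si, 0]), float(pts[si, 1])))
            tr["frames"].append(f)
            tr["last_frame"] = f
            used_t.add(ti)
            used_s.add(si)
        # retire stale tracks
        still = []
        for ti, tr in enumerate(active):
            if f - tr["last_frame"] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        for si in range(len(pts)):
            if si not in used_s:
                active.append(
                    {
                        "xy": [(float(pts[si, 0]), float(pts[si, 1]))],
                        "frames": [f],
                        "last_frame": f,
                    }
                )
    done.extend(active)

    tracks: list[Track] = []
    tid = 0
    for tr in done:
        if len(tr["xy"]) < min_length:
            continue
        xy = np.asarray(tr["xy"])
        t = np.asarray(tr["frames"], dtype=float) * frame_interval_s
        steps = np.hypot(*np.diff(xy, axis=0).T)
        path = float(steps.sum())
        duration = float(t[-1] - t[0])
        net = float(math.hypot(*(xy[-1] - xy[0])))
        if centre_um is not None and path > 0:
            r0 = math.hypot(xy[0, 0] - centre_um[0], xy[0, 1] - centre_um[1])
            r1 = math.hypot(xy[-1, 0] - centre_um[0], xy[-1, 1] - centre_um[1])
            centripetal = (r0 - r1) / path
        else:
            centripetal = float("nan")
        points = pd.DataFrame({"t_s": t, "x_um": xy[:, 0], "y_um": xy[:, 1]})
        tracks.append(
            Track(tid, points, path / duration if duration > 0 else 0.0, net, centripetal)
        )
        tid += 1
    return tracks


def pearson_colocalization(
    img_a: CalibratedImage | np.ndarray,
    img_b: CalibratedImage | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation Rr of paired pixel intensities within a mask.

    Raises :class:`UndefinedStatisticError` if either channel is constant
    within the mask (correlation undefined) or fewer than 2 pixels are
    analysed.
    """
    a = img_a.pixels if isinstance(img_a, CalibratedImage) else np.asarray(img_a)
    b = img_b.pixels if isinstance(img_b, CalibratedImage) else np.asarray(img_b)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    av, bv = a[mask].astype(float), b[mask].astype(float)
    if av.size < 2:
        raise UndefinedStatisticError("mask must cover >= 2 pixels")
    if av.std() == 0 or bv.std() == 0:
        raise UndefinedStatisticError("constant channel: Pearson Rr undefined")
    return float(np.corrcoef(av, bv)[0, 1])


def _sum_of_gaussians(x, *params):
    baseline = params[-1]
    out = np.full_like(x, baseline, dtype=float)
    for i in range(0, len(params) - 1, 3):
        amp, mu, sigma = params[i : i + 3]
        out += amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
    return out


def fit_fwhm(
    positions_nm: np.ndarray,
    intensities: np.ndarray,
    n_components: int = 1,
) -> FWHMFit:
    """Least-squares fit of ``n_components`` Gaussians plus a baseline.

    Components are initialised from the highest profile peaks (ties broken
    by leftmost position).  Raises :class:`FitError` for flat profiles or
    non-convergence, with the residual norm in the message.
    """
    x = np.asarray(positions_nm, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) < 5 * n_components:
        raise ValueError(f"profile needs >= {5 * n_components} points")
    if y.max() == y.min():
        raise FitError("flat profile: nothing to fit")
    baseline0 = float(y.min())
    # peaks: local maxima sorted by height desc, position asc
    interior = np.arange(1, len(y) - 1)
    is_peak = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1])
    cand = interior[is_peak]
    if len(cand) == 0:
        cand = np.array([int(np.argmax(y))])
    order = sorted(range(len(cand)), key=lambda i: (-y[cand[i]], x[cand[i]]))
    chosen = [cand[i] for i in order[:n_components]]
    while len(chosen) < n_components:
        chosen.append(int(np.argmax(y)))
    span = x.max() - x.min()
    p0 = []
    for idx in chosen:
        p0 += [float(y[idx] - baseline0), float(x[idx]), span / (8.0 * n_components)]
    p0.append(baseline0)
    try:
        popt, _ = curve_fit(_sum_of_gaussians, x, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        resid = float(np.linalg.norm(_sum_of_gaussians(x, *p0) - y))
        raise FitError(
            f"FWHM fit did not converge (initial residual norm {resid:.3g}): {exc}"
        ) from exc
    resid = float(np.linalg.norm(_sum_of_gaussians(x, *popt) - y))
    rows = []
    for i in range(0, len(popt) - 1, 3):
        amp, mu, sigma = popt[i], popt[i + 1], abs(popt[i + 2])
        rows.append(
            {
                "amplitude": float(amp),
                "centre_nm": float(mu),
                "sigma_nm": float(sigma),
                "fwhm_nm": float(sigma / FWHM_TO_SIGMA),
            }
        )
    comps = pd.DataFrame(rows).sort_values("centre_nm").reset_index(drop=True)
    return FWHMFit(comps, float(popt[-1]), resid)
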