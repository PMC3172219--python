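"""Synthetic image generators with exact ground truth.

Two families of generators are provided:

* **Exact binary fixtures** (:func:`make_mesh_fixture`) — regular grids of
  square or circular holes carved into an actin-positive field, with hole
  and penetrability geometry known analytically.  All fixture dimensions are
  integer multiples of the pixel size so downstream pixel-counting
  measurements are exact.
* **Realistic simulations** — noisy renderings of the structures seen at an
  NK-cell immune synapse imaged by structured illumination: a cortical actin
  mesh with a bright peripheral ring and a tunable central hole-area
  distribution, diffraction-limited granule spots in 3D stacks, annular
  receptor rings, and centripetally migrating microclusters in time-lapse
  movies.  Each generator returns the rendered image(s) plus a ground-truth
  table with one record per generated object.

The optical model is an isotropic Gaussian PSF (default FWHM 100 nm lateral,
250 nm axial, the resolution regime of 3D-SIM) with Poisson shot noise.
Sub-resolution objects are rendered as sphere-equivalent Gaussians whose
intrinsic FWHM equals the object diameter, so that PSF blur combines in
quadrature — the same model the granule-diameter estimator inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeneratorSpecError
from .images import CalibratedImage, CalibratedStack

__all__ = [
    "MeshFixtureSpec",
    "SimulationSpec",
    "make_mesh_fixture",
    "simulate_actin_image",
    "simulate_granule_stack",
    "simulate_ring_image",
    "simulate_microcluster_movie",
    "simulate_coclustered_pair",
    "sample_lateral_positions",
    "ACTIVATED_PRESET",
    "INHIBITORY_PRESET",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# exact binary mesh fixtures
# ---------------------------------------------------------------------------


@dataclass
class MeshFixtureSpec:
    """Regular grid of identical holes in an actin-positive field.

    ``hole_size_nm`` is the side (square) or diameter (circle) and must be
    an integer multiple of ``pixel_size_nm``; holes are laid out on a
    regular grid with at least ``margin_um`` clearance from the field
    border and must not overlap.
    """

    field_size_um: tuple[float, float] = (10.0, 10.0)
    pixel_size_nm: float = 10.0
    hole_shape: str = "square"
    hole_size_nm: float = 750.0
    n_holes: int = 18
    margin_um: float = 1.0

    def __post_init__(self) -> None:
        if self.hole_shape not in ("square", "circle"):
            raise GeneratorSpecError(f"unknown hole shape {self.hole_shape!r}")
        ratio = self.hole_size_nm / self.pixel_size_nm
        if abs(ratio - round(ratio)) > 1e-9:
            raise GeneratorSpecError(
                f"hole size {self.hole_size_nm} nm is not an integer multiple of "
                f"pixel size {self.pixel_size_nm} nm"
            )
        if self.n_holes < 0:
            raise GeneratorSpecError("n_holes must be >= 0")


def make_mesh_fixture(spec: MeshFixtureSpec) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render an exact binary mesh fixture (1 = actin, 0 = hole).

    Returns the binary image and a truth table with one row per hole
    (id, centroid in µm, pixel count, exact area in µm²).

    Raises
    ------
    GeneratorSpecError
        If the requested holes cannot be placed without overlapping or
        violating the border margin.
    """
    px_nm = spec.pixel_size_nm
    px_um = px_nm / 1000.0
    n_rows = int(round(spec.field_size_um[0] * 1000 / px_nm))
    n_cols = int(round(spec.field_size_um[1] * 1000 / px_nm))
    img = np.ones((n_rows, n_cols), dtype=float)
    records = []
    if spec.n_holes > 0:
        s = int(round(spec.hole_size_nm / px_nm))
        margin = int(round(spec.margin_um * 1000 / px_nm))
        grid = int(math.ceil(math.sqrt(spec.n_holes)))
        avail_r = n_rows - 2 * margin
        avail_c = n_cols - 2 * margin
        pitch_r = avail_r // grid
        pitch_c = avail_c // grid
        # need one hole + at least one actin pixel of separation per cell
        if pitch_r < s + 1 or pitch_c < s + 1 or avail_r <= 0 or avail_c <= 0:
            raise GeneratorSpecError(
                f"{spec.n_holes} holes of {spec.hole_size_nm} nm do not fit in "
                f"{spec.field_size_um} um with a {spec.margin_um} um margin"
            )
        k = 0
        for gr in range(grid):
            for gc in range(grid):
                if k >= spec.n_holes:
                    break
                r0 = margin + gr * pitch_r
                c0 = margin + gc * pitch_c
                if spec.hole_shape == "square":
                    img[r0 : r0 + s, c0 : c0 + s] = 0.0
                    n_px = s * s
                else:
                    rr, cc = np.mgrid[0:s, 0:s]
                    disc = (rr - (s - 1) / 2) ** 2 + (cc - (s - 1) / 2) ** 2 <= (s / 2) ** 2
                    img[r0 : r0 + s, c0 : c0 + s][disc] = 0.0
                    n_px = int(disc.sum())
                records.append(
                    {
                        "hole": k,
                        "x_um": (c0 + (s - 1) / 2) * px_um,
                        "y_um": (r0 + (s - 1) / 2) * px_um,
                        "n_pixels": n_px,
                        "area_um2": n_px * px_um**2,
                    }
                )
                k += 1
    truth = pd.DataFrame(
        records, columns=["hole", "x_um", "y_um", "n_pixels", "area_um2"]
    )
    return CalibratedImage(img, px_nm, "actin-fixture"), truth


# ---------------------------------------------------------------------------
# realistic simulations
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Parameters for the noisy synapse simulations.

    Actin mesh: a bright peripheral annulus between ``ring_inner_um`` and
    ``ring_outer_um`` plus an interior mesh whose hole areas are drawn from
    a log-normal with the stated mean/sd (µm²).  Granules: ``n_granules``
    spots with true diameters Normal(``granule_diameter_mean_nm``, sd)
    truncated at ``granule_diameter_min_nm`` and heights over 0-1 µm
    (``"uniform"`` or ``"docked"``, the latter placing two-thirds within
    250 nm of the surface).
    """

    field_size_um: float = 12.0
    pixel_size_nm: float = 40.0
    # actin mesh
    ring_inner_um: float = 8.0
    ring_outer_um: float = 10.0
    hole_area_mean_um2: float = 0.25
    hole_area_sd_um2: float = 0.15
    n_mesh_holes: int = 60
    # granules
    n_granules: int = 50
    granule_diameter_mean_nm: float = 251.0
    granule_diameter_sd_nm: float = 40.0
    granule_diameter_min_nm: float = 120.0
    granule_height_mode: str = "uniform"
    height_range_nm: tuple[float, float] = (0.0, 1000.0)
    z_step_nm: float = 125.0
    # optics / noise
    psf_fwhm_nm: float = 100.0
    psf_fwhm_axial_nm: float = 250.0
    photons: float = 200.0
    background: float = 10.0
    noise: bool = True
    blur: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm < 100.0:
            raise GeneratorSpecError(
                f"PSF FWHM {self.psf_fwhm_nm} nm is below the 100 nm microscope "
                "resolution limit"
            )
        for name in ("hole_area_mean_um2", "hole_area_sd_um2", "granule_diameter_mean_nm",
                     "granule_diameter_sd_nm", "z_step_nm"):
            if getattr(self, name) <= 0:
                raise GeneratorSpecError(f"{name} must be positive")
        if self.ring_outer_um > self.field_size_um:
            raise GeneratorSpecError(
                f"ring outer diameter {self.ring_outer_um} um exceeds the "
                f"{self.field_size_um} um field"
            )
        if self.granule_height_mode not in ("uniform", "docked"):
            raise GeneratorSpecError(f"unknown height mode {self.granule_height_mode!r}")


#: Activated-synapse mesh: opened-up central mesh (mean hole area 0.25 µm²).
ACTIVATED_PRESET = dict(hole_area_mean_um2=0.25, hole_area_sd_um2=0.15, n_mesh_holes=60)
#: Inhibitory/resting mesh: dense central mesh (mean hole area 0.05 µm²).
INHIBITORY_PRESET = dict(hole_area_mean_um2=0.05, hole_area_sd_um2=0.02, n_mesh_holes=60)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    var = sd**2
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _blur_and_shoot(field: np.ndarray, spec: SimulationSpec, rng, blur: bool = True
                    ) -> np.ndarray:
    px = spec.pixel_size_nm
    out = field
    if blur:
        sigma_px = spec.psf_fwhm_nm * FWHM_TO_SIGMA / px
        out = ndimage.gaussian_filter(out, sigma_px)
    if spec.noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    return out


def simulate_actin_image(spec: SimulationSpec) -> tuple[CalibratedImage, pd.DataFrame]:
    """Simulate an F-actin synapse image: peripheral ring + central mesh.

    The binary truth mesh is built by carving non-overlapping circular holes
    (areas drawn log-normally) into a uniformly actin-positive interior; the
    intensity image adds a bright annulus at the stated ring diameters, PSF
    blur and Poisson noise.  The truth table lists the realised per-hole
    pixel areas of the carved binary mesh.
    """
    rng = np.random.default_rng(spec.seed)
    px_um = spec.pixel_size_nm / 1000.0
    n = int(round(spec.field_size_um * 1000 / spec.pixel_size_nm))
    centre = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    radius_um = np.hypot(rr - centre, cc - centre) * px_um

    cell = radius_um <= spec.ring_outer_um / 2.0
    ring = (radius_um >= spec.ring_inner_um / 2.0) & cell
    interior = radius_um < spec.ring_inner_um / 2.0

    # carve holes into the interior mesh
    mesh = interior.copy()  # True = actin
    mu, sigma = _lognormal_params(spec.hole_area_mean_um2, spec.hole_area_sd_um2)
    areas = np.exp(rng.normal(mu, sigma, size=spec.n_mesh_holes))
    hole_mask = np.zeros((n, n), dtype=bool)
    placed = []
    r_lim = spec.ring_inner_um / 2.0
    for a in areas:
        r_um = math.sqrt(a / math.pi)
        r_px = max(r_um / px_um, 1.0)
        for _ in range(200):
            rho = r_lim * math.sqrt(rng.uniform()) * 0.92
            theta = rng.uniform(0, 2 * math.pi)
            hr = centre + (rho / px_um) * math.sin(theta)
            hc = centre + (rho / px_um) * math.cos(theta)
            if rho + r_um > r_lim - 2 * px_um:
                continue
            d2 = (rr - hr) ** 2 + (cc - hc) ** 2
            disc = d2 <= r_px**2
            # keep a 1-px actin rim between holes
            dilated = d2 <= (r_px + 2.0) ** 2
            if not (hole_mask & dilated).any():
                hole_mask |= disc
                placed.append((hc * px_um, hr * px_um, int(disc.sum())))
                break
    mesh &= ~hole_mask

    truth = pd.DataFrame(
        [
            {"hole": i, "x_um": x, "y_um": y, "n_pixels": npx,
             "area_um2": npx * px_um**2}
            for i, (x, y, npx) in enumerate(placed)
        ],
        columns=["hole", "x_um", "y_um", "n_pixels", "area_um2"],
    )

    field = np.zeros((n, n), dtype=float)
    field += spec.background
    field[mesh] += spec.photons
    field[ring] += 2.5 * spec.photons
    img = _blur_and_shoot(field, spec, rng, blur=spec.blur)
    out = CalibratedImage(img, spec.pixel_size_nm, "actin")
    out.truth_mask = mesh | ring  # binary truth: True = actin-positive
    return out, truth


def _granule_sigmas_px(diameter_nm: float, spec: SimulationSpec) -> tuple[float, float]:
    """Lateral and axial Gaussian sigmas (px / nm) of a rendered granule."""
    fwhm_lat = math.sqrt(diameter_nm**2 + spec.psf_fwhm_nm**2)
    fwhm_ax = math.sqrt(diameter_nm**2 + spec.psf_fwhm_axial_nm**2)
    return (
        fwhm_lat * FWHM_TO_SIGMA / spec.pixel_size_nm,  # in px
        fwhm_ax * FWHM_TO_SIGMA,  # in nm
    )


def simulate_granule_stack(
    spec: SimulationSpec, positions: np.ndarray | None = None
) -> tuple[CalibratedStack, pd.DataFrame]:
    """Render a z-stack of granule spots with known centroids and diameters.

    Granules are placed on a jittered grid (well separated) unless explicit
    ``positions`` (µm, shape (n, 2) as x, y) are given; heights follow the
    spec's height mode.  Each granule is a 3D Gaussian whose intrinsic FWHM
    equals its true diameter, blurred by the PSF in quadrature.

    Raises
    ------
    GeneratorSpecError
        If a granule would be centred outside the field.
    """
    rng = np.random.default_rng(spec.seed)
    px_nm = spec.pixel_size_nm
    px_um = px_nm / 1000.0
    n = int(round(spec.field_size_um * 1000 / px_nm))
    z_lo, z_hi = spec.height_range_nm
    heights_nm = np.arange(z_lo, z_hi + 0.5 * spec.z_step_nm, spec.z_step_nm)
    n_z = len(heights_nm)

    m = spec.n_granules
    if positions is None and m > 0:
        # jittered grid with >= 1.2 um pitch, 1 um margin
        pitch = max(1.5, 1.2)
        margin = 1.0
        per_side = int((spec.field_size_um - 2 * margin) // pitch)
        if per_side**2 < m:
            raise GeneratorSpecError(
                f"{m} granules do not fit well-separated in a "
                f"{spec.field_size_um} um field"
            )
        xs, ys = np.meshgrid(
            margin + pitch * (np.arange(per_side) + 0.5),
            margin + pitch * (np.arange(per_side) + 0.5),
        )
        sites = np.column_stack([xs.ravel(), ys.ravel()])
        sites = sites[rng.permutation(len(sites))[:m]]
        jitter = rng.uniform(-0.25, 0.25, size=(m, 2))
        positions = sites + jitter
    elif positions is None:
        positions = np.zeros((0, 2))
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != m:
        raise GeneratorSpecError("positions must match n_granules")
    if m and (
        (positions < 0).any()
        or (positions >= spec.field_size_um).any()
    ):
        raise GeneratorSpecError("granule centred outside the field")

    diameters = rng.normal(spec.granule_diameter_mean_nm, spec.granule_diameter_sd_nm, m)
    diameters = np.clip(diameters, spec.granule_diameter_min_nm, None)
    if spec.granule_height_mode == "docked":
        docked = rng.uniform(size=m) < 2.0 / 3.0
        z = np.where(
            docked,
            rng.uniform(z_lo, min(250.0, z_hi), m),
            rng.uniform(min(250.0, z_hi), z_hi, m),
        )
    else:
        z = rng.uniform(z_lo, z_hi, m)

    stack = np.full((n_z, n, n), float(spec.background))
    half = 15  # px window for local rendering
    for (x_um, y_um), d, zc in zip(positions, diameters, z):
        sig_lat_px, sig_ax_nm = _granule_sigmas_px(d, spec)
        c = x_um / px_um
        r = y_um / px_um
        r0, r1 = max(0, int(r) - half), min(n, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(n, int(c) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        lat = np.exp(-((xx - c) ** 2 + (yy - r) ** 2) / (2 * sig_lat_px**2))
        ax = np.exp(-((heights_nm - zc) ** 2) / (2 * sig_ax_nm**2))
        stack[:, r0:r1, c0:c1] += spec.photons * ax[:, None, None] * lat[None]
    if spec.noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)

    planes = [CalibratedImage(p, px_nm, "granules") for p in stack]
    out = CalibratedStack(planes, spec.z_step_nm, z0_offset_nm=z_lo)
    truth = pd.DataFrame(
        {
            "granule": np.arange(m),
            "x_um": positions[:, 0] if m else np.array([]),
            "y_um": positions[:, 1] if m else np.array([]),
            "z_nm": z,
            "diameter_nm": diameters,
        }
    )
    return out, truth


def simulate_ring_image(
    inner_diameter_um: float,
    outer_diameter_um: float,
    field_size_um: float = 12.0,
    pixel_size_nm: float = 40.0,
    intensity: float = 200.0,
    background: float = 0.0,
    noise: bool = False,
    seed: int = 0,
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render an annulus of uniform intensity between two diameters.

    ``inner_diameter_um = 0`` degenerates to a filled disc.  Truth records
    both diameters.
    """
    if inner_diameter_um < 0 or inner_diameter_um >= outer_diameter_um:
        raise GeneratorSpecError(
            f"need 0 <= inner < outer, got ({inner_diameter_um}, {outer_diameter_um})"
        )
    if outer_diameter_um > field_size_um:
        raise GeneratorSpecError("ring outer diameter exceeds the field")
    rng = np.random.default_rng(seed)
    px_um = pixel_size_nm / 1000.0
    n = int(round(field_size_um * 1000 / pixel_size_nm))
    centre = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    radius_um = np.hypot(rr - centre, cc - centre) * px_um
    annulus = (radius_um >= inner_diameter_um / 2.0) & (radius_um <= outer_diameter_um / 2.0)
    img = np.full((n, n), float(background))
    img[annulus] += intensity
    if noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    truth = pd.DataFrame(
        [{"inner_diameter_um": inner_diameter_um, "outer_diameter_um": outer_diameter_um,
          "x_um": centre * px_um, "y_um": centre * px_um}]
    )
    return CalibratedImage(img, pixel_size_nm, "ring"), truth


def sample_lateral_positions(
    region_mask: np.ndarray,
    pixel_size_nm: float,
    n: int,
    rng,
    on_mask: np.ndarray | None = None,
    on_fraction: float = 0.0,
) -> np.ndarray:
    """Sample granule (x, y) positions (µm) over a region.

    A fraction ``on_fraction`` of positions is drawn from ``on_mask``
    (e.g. the penetrable map, emulating granules docked at opened-mesh
    domains); the rest are uniform over the region.  Returns (n, 2) x/y µm.
    """
    px_um = pixel_size_nm / 1000.0
    idx_region = np.argwhere(region_mask)
    out = np.empty((n, 2))
    on = (rng.uniform(size=n) < on_fraction) if on_mask is not None else np.zeros(n, bool)
    idx_on = np.argwhere(on_mask & region_mask) if on_mask is not None else None
    for i in range(n):
        pool = idx_on if (on[i] and idx_on is not None and len(idx_on)) else idx_region
        r, c = pool[rng.integers(0, len(pool))]
        out[i] = (c * px_um, r * px_um)
    return out


def simulate_coclustered_pair(
    target_rr: float = 0.7,
    n_clusters: int = 20,
    field_size_um: float = 12.0,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
) -> tuple[CalibratedImage, CalibratedImage]:
    """Two channels sharing clustered structure with independent noise.

    Both channels image the same cluster field S with independent Gaussian
    noise whose variance is chosen from the signal variance so that the
    expected Pearson correlation is ``target_rr``
    (corr = var(S) / (var(S) + var(noise)) for equal independent noise).
    """
    if not (0 < target_rr < 1):
        raise GeneratorSpecError("target_rr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    px_um = pixel_size_nm / 1000.0
    n = int(round(field_size_um * 1000 / pixel_size_nm))
    rr_idx, cc_idx = np.mgrid[0:n, 0:n]
    signal = np.zeros((n, n))
    sig_px = 400.0 * FWHM_TO_SIGMA / pixel_size_nm
    for _ in range(n_clusters):
        r0, c0 = rng.uniform(0.15 * n, 0.85 * n, 2)
        signal += 100.0 * np.exp(
            -((rr_idx - r0) ** 2 + (cc_idx - c0) ** 2) / (2 * sig_px**2)
        )
    var_s = signal.var()
    sd_noise = math.sqrt(var_s * (1.0 - target_rr) / target_rr)
    a = signal + rng.normal(0, sd_noise, signal.shape)
    b = signal + rng.normal(0, sd_noise, signal.shape)
    offset = -min(a.min(), b.min(), 0.0)
    return (
        CalibratedImage(a + offset, pixel_size_nm, "channel-A"),
        CalibratedImage(b + offset, pixel_size_nm, "channel-B"),
    )


def simulate_microcluster_movie(
    n_clusters: int,
    speed_range_um_s: tuple[float, float] = (0.25, 1.0),
    n_frames: int = 10,
    frame_interval_s: float = 1.0,
    field_size_um: float = 14.0,
    pixel_size_nm: float = 100.0,
    start_radius_um: float = 6.0,
    spot_fwhm_nm: float = 400.0,
    photons: float = 300.0,
    background: float = 10.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[list[CalibratedImage], pd.DataFrame]:
    """Time-lapse of microclusters migrating radially inward.

    Clusters start on a circle of ``start_radius_um`` about the field centre
    at random angles and move centripetally at constant per-cluster speeds
    drawn uniformly from ``speed_range_um_s``.  Truth lists every
    per-frame position and the per-cluster speed.
    """
    if frame_interval_s <= 0:
        raise GeneratorSpecError("frame interval must be > 0")
    lo, hi = speed_range_um_s
    if hi * frame_interval_s > field_size_um / 2.0:
        raise GeneratorSpecError("per-frame step exceeds the field radius")
    rng = np.random.default_rng(seed)
    px_um = pixel_size_nm / 1000.0
    n = int(round(field_size_um * 1000 / pixel_size_nm))
    centre_um = (n - 1) / 2.0 * px_um
    speeds = rng.uniform(lo, hi, n_clusters)
    # evenly spaced starting angles with jitter: clusters form all around the
    # periphery and stay laterally resolvable
    if n_clusters:
        angles = (2 * math.pi / n_clusters) * (
            np.arange(n_clusters) + rng.uniform(0.1, 0.9, n_clusters)
        )
    else:
        angles = np.zeros(0)
    sig_px = spot_fwhm_nm * FWHM_TO_SIGMA / pixel_size_nm

    frames: list[CalibratedImage] = []
    rows = []
    rr, cc = np.mgrid[0:n, 0:n]
    for f in range(n_frames):
        t = f * frame_interval_s
        field = np.full((n, n), float(background))
        for k in range(n_clusters):
            r_k = max(start_radius_um - speeds[k] * t, 0.0)
            x = centre_um + r_k * math.cos(angles[k])
            y = centre_um + r_k * math.sin(angles[k])
            field += photons * np.exp(
                -((cc * px_um - x) ** 2 + (rr * px_um - y) ** 2) / (2 * (sig_px * px_um) ** 2)
            )
            rows.append({"cluster": k, "frame": f, "t_s": t, "x_um": x, "y_um": y,
                         "speed_um_s": speeds[k]})
        if noise:
            field = rng.poisson(np.clip(field, 0, None)).astype(float)
        frames.append(CalibratedImage(field, pixel_size_nm, "microclusters"))
    truth = pd.DataFrame(rows, columns=["cluster", "frame", "t_s", "x_um", "y_um",
                                        "speed_um_s"])
    return frames, truth
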