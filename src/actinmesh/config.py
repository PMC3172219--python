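"""Pipeline configuration: one YAML file, physically motivated defaults.

Defaults follow the imaging regime the pipeline was designed for: 3D
structured-illumination microscopy with ~100 nm lateral / ~250 nm axial
resolution, 40 nm reconstructed pixels, z-stacks covering the first 1 µm
above the activating surface, and lytic granules of 100-800 nm diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters in one place.

    Attributes
    ----------
    pixel_size_nm : default in-plane calibration when files carry none.
    segmentation_method : ``"otsu"``, ``"percentile"`` or ``"fixed"``.
    segmentation_param : percentile (0-100) or fixed threshold, per method.
    granule_diameter_range_nm : admissible estimated granule diameters; the
        lower edge doubles as the microscope resolution floor.
    strata_edges_nm : axial bin edges for granule height strata.
    heatmap_bounds_um2 : hole-area colour-scale clip (blue .. red).
    psf_fwhm_nm / psf_fwhm_axial_nm : point-spread FWHM used for blur and
        for quadrature correction of spot sizes.
    height_cap_nm : stacks are analysed up to this height above the surface.
    ring_ratio : peripheral-peak to central-baseline intensity ratio that
        defines presence of a ring.
    min_hole_area_um2 : resolution floor below which mesh holes are
        discarded (0.01 µm² ~ the (100 nm)² resolution limit).
    """

    pixel_size_nm: float = 40.0
    segmentation_method: str = "otsu"
    segmentation_param: float | None = None
    granule_diameter_range_nm: tuple[float, float] = (100.0, 800.0)
    strata_edges_nm: tuple[float, ...] = (0.0, 250.0, 500.0, 750.0, 1000.0)
    heatmap_bounds_um2: tuple[float, float] = (0.01, 3.0)
    psf_fwhm_nm: float = 100.0
    psf_fwhm_axial_nm: float = 250.0
    height_cap_nm: float = 1000.0
    ring_ratio: float = 2.0
    min_hole_area_um2: float = 0.01
    seed: int = 0
    outdir: str = "actinmesh_out"

    def __post_init__(self) -> None:
        lo, hi = self.granule_diameter_range_nm
        if not (0 < lo < hi):
            raise ValueError(f"invalid granule diameter range ({lo}, {hi})")
        edges = tuple(self.strata_edges_nm)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"strata edges must be strictly increasing: {edges}")
        if self.segmentation_method not in ("otsu", "percentile", "fixed"):
            raise ValueError(f"unknown segmentation method {self.segmentation_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("granule_diameter_range_nm", "strata_edges_nm", "heatmap_bounds_um2"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
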