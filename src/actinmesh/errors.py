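"""Exception hierarchy for the actinmesh pipeline.

All pipeline errors derive from :class:`ActinMeshError` so callers can catch
one base class; subclasses distinguish calibration, format, detection and
statistical failure modes.
"""


class ActinMeshError(Exception):
    """Base class for all actinmesh errors."""


class CalibrationError(ActinMeshError):
    """Physical calibration (pixel size, z-step) missing or invalid."""


class ImageFormatError(ActinMeshError):
    """Input file is not a readable image or has inconsistent planes."""


class GeneratorSpecError(ActinMeshError, ValueError):
    """A synthetic-data specification is geometrically impossible."""


class NoCellError(ActinMeshError):
    """No cell footprint could be segmented from the image."""


class NoRingError(ActinMeshError):
    """A peripheral ring is required but none was detected/declared."""


class DegenerateThresholdError(ActinMeshError):
    """Automatic thresholding is undefined (e.g. constant image)."""


class DetectionError(ActinMeshError):
    """Spot/blob detection failed (saturated or empty data)."""


class UndefinedStatisticError(ActinMeshError):
    """A summary statistic is undefined for the given input (e.g. empty table)."""


class FitError(ActinMeshError):
    """A model fit failed to converge."""
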