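"""Exception hierarchy.

All package-specific failures derive from :class:`MTSeamError` so callers
(and the CLI, which maps them to exit code 3) can catch one type.
"""


class MTSeamError(Exception):
    """Base class for all mtseam errors."""


class InvalidLatticeError(MTSeamError):
    """Lattice parameters are geometrically impossible (n_pf < 2, rise <= 0, ...)."""


class GeometryError(MTSeamError):
    """Voxel-grid geometries that must match do not (shape, voxel size, origin)."""


class EmptyMaskError(MTSeamError):
    """A mask operation produced an empty support."""


class EmptyDensityError(MTSeamError):
    """A density render received no points inside the frame."""


class ParameterError(MTSeamError):
    """A parameter value is outside its documented domain."""


class DegenerateCorrelationError(MTSeamError):
    """Correlation objective undefined (zero variance inside the mask)."""


class DetectionError(MTSeamError):
    """Protofilament detection failed (too few components, no contrast)."""


class FitError(MTSeamError):
    """Ellipse (or other model) fit is degenerate."""


class RegressionError(MTSeamError):
    """Regression input is degenerate (zero variance in the predictor)."""


class SpecError(MTSeamError):
    """A synthetic-map specification is internally inconsistent."""
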