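"""Exception hierarchy shared across the pipeline stages."""


class ValveMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidProtocolError(ValveMechError):
    """A requested loading state lies outside the tensile protocol (e.g. stretch < 1)."""


class DegenerateSceneError(ValveMechError):
    """A synthetic scene contains no renderable content inside the frame."""


class InvalidSpecError(ValveMechError):
    """A generator specification violates its invariants."""


class EquilibriumFailureError(ValveMechError):
    """The two-post force balance has no root in the physical deflection bracket."""


class InvalidGeometryError(ValveMechError):
    """A post geometry has a nonpositive dimension or modulus."""


class InvalidSpecimenError(ValveMechError):
    """A specimen cross-section dimension is nonpositive."""


class FitFailureError(ValveMechError):
    """Constitutive fit failed to converge after bounded restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DataQualityError(ValveMechError):
    """Input data cannot support the requested fit (constant or decreasing stress)."""


class InvalidPolygonError(ValveMechError):
    """A cell outline is not a simple polygon with at least three vertices."""


class InsufficientDataError(ValveMechError):
    """Too few frames, groups, or samples for the requested analysis."""


class InvalidSeedError(ValveMechError):
    """A fiducial seed point lies outside the image raster."""


class UnstablePairError(ValveMechError):
    """A marker pair's initial projected separation is too small for strain estimation."""


class ZeroPowerError(ValveMechError):
    """An image has no spectral power (constant raster)."""


class InvalidMaskError(ValveMechError):
    """A leaflet mask is empty or mismatched in shape."""


class StainConfigError(ValveMechError):
    """A stain profile names an unknown constituent or channel rule."""


class NormalizationError(ValveMechError):
    """Reference group for normalization is empty or has zero mean."""


class DegenerateDesignError(ValveMechError):
    """Regression design is degenerate (all abscissae equal)."""


class CompressionWarning(UserWarning):
    """Post separation below rest separation: specimen in compression, outside analysis range."""
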