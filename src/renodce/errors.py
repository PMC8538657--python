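"""Exception hierarchy.

Every reader/operation raises a specific subclass of :class:`RenoDCEError`
so callers can distinguish malformed inputs from configuration mistakes or
degenerate data.
"""


class RenoDCEError(Exception):
    """Base class for all package errors."""


class FormatError(RenoDCEError):
    """On-disk artifact is malformed (wrong dimensionality, bad codes, missing sidecar field)."""


class ConfigurationError(RenoDCEError):
    """A configuration value is missing, unknown or inconsistent."""


class GeometryError(RenoDCEError):
    """Phantom geometry does not fit the requested matrix (or kidneys overlap)."""


class ParameterError(RenoDCEError, ValueError):
    """A numeric parameter is out of its admissible range."""


class ShapeError(RenoDCEError, ValueError):
    """Array arguments have incompatible shapes."""


class DomainError(RenoDCEError, ValueError):
    """A value lies outside the mathematical domain of the operation."""


class EmptyRegionError(RenoDCEError):
    """An operation that needs at least one voxel received an empty region."""


class NoEnhancementError(RenoDCEError):
    """The dynamic series shows no contrast enhancement."""


class MissingClassError(RenoDCEError):
    """A required tissue class is absent from the training labels."""


class ProvenanceError(RenoDCEError):
    """Model artifacts from different training cohorts were combined."""


class StateError(RenoDCEError):
    """An object is used before reaching the required state (e.g. untrained network)."""
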