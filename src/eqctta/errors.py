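"""Exception hierarchy shared across the pipeline.

Every error raised on purpose by this package derives from :class:`EqcttaError`
so callers can catch pipeline failures without masking programming errors.
"""


class EqcttaError(Exception):
    """Base class for all errors raised by eqctta."""


class GeometryError(EqcttaError):
    """Lattice mismatch, bad pixel spacing, or an empty/invalid mask."""


class DataError(EqcttaError):
    """Pixel data violates HU semantics (non-finite or out of range)."""


class SamplingError(EqcttaError):
    """Too few pixels remain in an ROI to compute stable statistics."""


class PairingError(EqcttaError):
    """Texture vectors paired for subtraction disagree on SSF or region."""


class EnhancementError(EqcttaError):
    """Blood-pool attenuation did not rise between phases; equilibrium failed."""


class UndefinedCorrelationError(EqcttaError):
    """Rank correlation is undefined (zero variance in an input vector)."""


class InputError(EqcttaError):
    """Malformed tabular input (duplicate ids, missing columns, bad values)."""


class ResolutionWarning(UserWarning):
    """Filter scale is close to or below the pixel size; responses unreliable."""
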