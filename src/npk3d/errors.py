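"""Exception hierarchy for the npk3d pipeline."""


class Npk3dError(Exception):
    """Base class for all pipeline errors."""


class DimensionError(Npk3dError, ValueError):
    """Array shapes are incompatible for the requested operation."""


class DegenerateInputError(Npk3dError, ValueError):
    """Input carries no usable signal (constant image, symmetric spectrum, ...)."""


class CalibrationError(Npk3dError, RuntimeError):
    """Turntable self-calibration failed (missing stickers, bad geometry)."""


class IllConditionedAxisError(CalibrationError):
    """Sticker chords are too short or too parallel to define the rotation axis."""


class AmbiguousAngleError(Npk3dError, ValueError):
    """Axis direction has a vanishing projection; Euler angles undefined."""


class EmptyCloudError(Npk3dError, ValueError):
    """An operation that needs points received an empty cloud."""


class RegistrationFailureError(Npk3dError, RuntimeError):
    """ICP or image registration could not establish correspondences."""


class AlignmentError(Npk3dError, ValueError):
    """Landmark-based rigid alignment is under-determined (too few / collinear pairs)."""


class OverlapUndefinedError(Npk3dError, ValueError):
    """Spectral overlap is undefined because the reference mask is empty."""
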