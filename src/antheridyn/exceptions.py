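"""Exception hierarchy.

Every error raised by the package derives from :class:`AntheridynError` so
callers (and the CLI) can distinguish validation problems from bugs.
"""


class AntheridynError(ValueError):
    """Base class for all antheridyn errors."""


class OrientationError(AntheridynError):
    """Anchor configuration does not define a valid orientation."""


class CorrespondenceError(AntheridynError):
    """Landmark correspondence across specimens or frames is broken."""


class GeometryError(AntheridynError):
    """Degenerate or self-intersecting geometric input."""


class InputError(AntheridynError):
    """An operation received structurally invalid input."""


class CalibrationError(AntheridynError):
    """The factor-mixture calibration has no feasible solution."""


class GenerationError(AntheridynError):
    """Synthetic-data generation produced an infeasible configuration."""


class ValidationError(AntheridynError):
    """A file failed schema validation; message names file, row and rule."""
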