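"""Exception hierarchy.

All invalid-configuration and invalid-input conditions raise subclasses of
:class:`TransfcError`, so callers (and the CLI exit-code mapping) can
distinguish user error from internal failure.
"""


class TransfcError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TransfcError, ValueError):
    """A configuration value violates an invariant (bands, grid, rates)."""


class InvalidInputError(TransfcError, ValueError):
    """Runtime input violates a precondition (shapes, empty masks, ranks)."""


class DegenerateSliceError(InvalidInputError):
    """A coronal slice cannot be segmented (too few voxels / zero extent)."""


class ZeroVarianceError(InvalidInputError):
    """A statistic is undefined because its input has zero variance."""
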