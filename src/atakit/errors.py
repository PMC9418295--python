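"""Exception hierarchy.

Everything raised on purpose derives from :class:`AtakitError` so callers can
catch pipeline failures without masking programming errors.
"""


class AtakitError(Exception):
    """Base class for all errors raised by atakit."""


class FormatError(AtakitError, ValueError):
    """Malformed input file (ragged alignment, duplicate ids, bad CSV)."""


class MappingError(AtakitError, ValueError):
    """Unified-position anchoring failed (anchor outside reference, unmapped position)."""


class ConfigurationError(AtakitError, ValueError):
    """Inconsistent simulation or analysis configuration."""


class InsufficientDataError(AtakitError, ValueError):
    """Too few data points for the requested fit."""


class NoTransitionError(AtakitError, ValueError):
    """Melting curve shows no interior unfolding transition."""
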