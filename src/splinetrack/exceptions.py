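"""Exception hierarchy shared across the toolkit."""


class SplinetrackError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SplinetrackError, ValueError):
    """A file on disk does not match its declared format or is internally
    inconsistent (e.g. gradient-table length vs. number of volumes)."""


class ValidationError(SplinetrackError, ValueError):
    """An in-memory object violates a domain invariant."""


class ConfigurationError(SplinetrackError, ValueError):
    """Inputs are well-formed but insufficient for the requested computation
    (e.g. a rank-deficient tensor design matrix)."""
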