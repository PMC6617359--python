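"""Exception hierarchy shared across the package."""


class SmokefuseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SmokefuseError, ValueError):
    """Input data violates a declared invariant (negative PM2.5, duplicate keys, ...)."""


class FormatError(SmokefuseError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class MissingDateError(SmokefuseError, ValueError):
    """A requested date is not covered by a field stack."""


class ParameterError(SmokefuseError, ValueError):
    """A configuration or simulation parameter is out of its admissible range."""


class UndefinedMetricError(SmokefuseError, ValueError):
    """A metric is mathematically undefined for the given inputs."""


class DegenerateFoldError(SmokefuseError, ValueError):
    """A cross-validation fold has a constant training target."""
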