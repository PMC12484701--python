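"""Exception types used across the package."""


class SeegkitError(Exception):
    """Base class for all package errors."""


class FormatError(SeegkitError, ValueError):
    """A file could not be parsed as the expected format."""


class MetadataError(SeegkitError, ValueError):
    """Channel metadata is inconsistent with the recording."""


class ParameterError(SeegkitError, ValueError):
    """An argument violates a documented precondition."""


class StatisticsError(SeegkitError, ValueError):
    """Too little data to compute the requested statistic."""


class ConfigError(SeegkitError, ValueError):
    """A configuration file or scenario failed validation."""
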