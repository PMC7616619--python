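"""Exception hierarchy used across the package."""


class DmardMonitorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DmardMonitorError):
    """A configuration value, drug/test label or scope is invalid."""


class DataError(DmardMonitorError):
    """An input record is malformed (e.g. an unparseable date)."""


class InsufficientDataError(DmardMonitorError):
    """Too little data to compute the requested statistic."""
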