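"""Exception hierarchy shared across the package."""


class CvRatioError(Exception):
    """Base class for package errors."""


class ConfigurationError(CvRatioError):
    """Invalid configuration: unknown scenario, unmappable header, bad criteria."""


class DataError(CvRatioError):
    """Input data that cannot be analyzed (unreadable file, empty table)."""
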