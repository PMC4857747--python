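"""Exception hierarchy shared across the package."""


class XenomirError(Exception):
    """Base class for all package-specific errors."""


class InputError(XenomirError):
    """Malformed input data (files, matrices, sequences)."""


class ConfigError(XenomirError):
    """Invalid configuration or parameter values."""


class ZeroVarianceError(XenomirError):
    """Paired differences have zero variance; the t statistic is undefined.

    Raised instead of reporting p = 0 or p = 1 so that constant data is
    surfaced as a degenerate case rather than a spuriously perfect result.
    """
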