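"""Exception types shared across the package."""


class HemowaveError(Exception):
    """Base class for package errors."""


class ChannelError(HemowaveError, KeyError):
    """A required channel is missing or unknown."""


class ConfigurationError(HemowaveError, ValueError):
    """A configuration value is inconsistent (e.g. non-integer window length)."""


class FormatError(HemowaveError, ValueError):
    """An on-disk record is malformed."""
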