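"""Exception hierarchy shared across the pipeline.

Validation failures (exit code 2 in the CLI) are kept distinct from I/O
failures (exit code 3) so batch runs can tell malformed data from missing
files.
"""


class GazepipeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GazepipeError):
    """A file does not match the documented tabular dialect."""


class ValidationError(GazepipeError):
    """Data was parsed but violates a declared invariant."""


class ConfigError(GazepipeError):
    """A configuration value is out of range or inconsistent."""
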