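"""Exception hierarchy.

Two broad classes matter to callers (and to the CLI exit codes): problems
with a configuration (bad fractions, bad grid, bad phantom spec) and
problems with the data itself (empty mask, misaligned images, degenerate
intensity ranges).
"""


class CallomapError(Exception):
    """Base class for all package errors."""


class ConfigError(CallomapError):
    """Invalid configuration: fractions, grid layout, phantom spec, CLI options."""


class DataError(CallomapError):
    """Invalid or degenerate input data: masks, images, tables."""
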