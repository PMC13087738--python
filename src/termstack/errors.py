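"""Exception types shared across the package.

All are subclasses of builtins so callers can catch broadly (``ValueError``,
``IndexError``) or precisely.
"""


class ConfigurationError(ValueError):
    """A parameter value is outside its documented domain."""


class FormatError(ValueError):
    """On-disk bytes or a style string do not match the expected format."""


class BoundsError(IndexError):
    """An index is outside the bounds of the bound image axis."""
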