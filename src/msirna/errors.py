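"""Exception hierarchy.

All user-facing failures derive from :class:`MsirnaError` so the CLI can map
them to exit code 1 without leaking stack traces.
"""


class MsirnaError(Exception):
    """Base class for all msirna errors."""


class ValidationError(MsirnaError):
    """Input violates a structural or statistical precondition."""


class ParseError(MsirnaError):
    """A file could not be parsed; the message names the offending location."""


class StateError(MsirnaError):
    """An operation was applied to data in the wrong transformation state."""


class ModelFormatError(MsirnaError):
    """A model file is truncated, version-mismatched, or otherwise invalid."""
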