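"""Exception hierarchy shared by both conversion directions."""


class ConversionError(Exception):
    """Base class for all converter-raised errors."""


class XmlParseError(ConversionError):
    """Source is not well-formed XML; message names line and column."""


class StructureError(ConversionError):
    """Well-formed XML that lacks the required document skeleton."""


class ReferenceResolutionError(ConversionError):
    """An OID reference does not resolve; message names the OID."""


class InvariantViolation(ConversionError):
    """A value object violates its invariants; raised before any output."""


class StateError(ConversionError):
    """An operation was called on an object in the wrong state."""
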