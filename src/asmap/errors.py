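"""Exception types shared across the package."""


class AsmapError(Exception):
    """Base class for all package errors."""


class ValidationError(AsmapError, ValueError):
    """A container or configuration violates one of its invariants."""


class FormatError(AsmapError, ValueError):
    """A file does not parse under the named standard."""
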