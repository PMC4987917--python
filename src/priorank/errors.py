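"""Exception hierarchy."""


class PriorankError(Exception):
    """Base class for all priorank errors."""


class FormatError(PriorankError):
    """A file could not be parsed (malformed line, bad header, ...)."""


class ValidationError(PriorankError, ValueError):
    """Inputs violate a documented precondition or invariant."""
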