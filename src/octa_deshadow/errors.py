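"""Exception types shared across the package."""


class FormatError(ValueError):
    """On-disk data does not match its declared format or metadata."""


class ValidationError(ValueError):
    """An in-memory object or argument violates a documented precondition."""
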