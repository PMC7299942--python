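"""Exception hierarchy for the package."""


class StereogoldError(Exception):
    """Base class for package errors."""


class FormatError(StereogoldError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(StereogoldError):
    """Input data violate a documented invariant (e.g. duplicate tower IDs)."""
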