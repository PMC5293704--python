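"""Exception hierarchy for the dfp package."""


class DfpError(Exception):
    """Base class for all package errors."""


class FormatError(DfpError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(DfpError):
    """Input data violates a structural invariant (lengths, alphabets, ids)."""


class UsageError(DfpError):
    """A parameter is outside its documented domain."""


class InputError(DfpError):
    """Input is structurally valid but unusable (empty, too small)."""


class CapabilityError(DfpError):
    """An optional backend required for this operation is not installed."""
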