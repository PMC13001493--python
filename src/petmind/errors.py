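"""Exception hierarchy.

All package-raised errors derive from :class:`PetmindError` so callers can
catch everything from one base, while the CLI maps validation-type failures
and runtime failures to distinct exit codes.
"""


class PetmindError(Exception):
    """Base class for all errors raised by petmind."""


class ValidationError(PetmindError):
    """Input data violates a structural contract (shape, finiteness, order)."""


class ConfigurationError(PetmindError):
    """A configuration object is internally inconsistent."""


class DegenerateInputError(PetmindError):
    """Input is structurally valid but the requested quantity is undefined
    on it (e.g. all time-activity curves identical, constant correlation
    vectors, zero-variance features)."""
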