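"""Exception hierarchy used across the package."""


class FMAError(Exception):
    """Base class for all package errors."""


class FormatError(FMAError, ValueError):
    """A file does not conform to the expected on-disk schema."""


class ValidationError(FMAError, ValueError):
    """Input data violate a documented invariant."""


class ParameterError(FMAError, ValueError):
    """A configuration or algorithm parameter is out of range."""


class DegenerateInputError(FMAError, ValueError):
    """Input is formally valid but the quantity is undefined on it
    (e.g. an all-zero speed profile handed to a smoothness metric)."""


class LookupFMAError(FMAError, KeyError):
    """An item or motion code is not present in the registry."""
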