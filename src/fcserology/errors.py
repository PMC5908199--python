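"""Exception hierarchy shared across the package."""


class FcSerologyError(Exception):
    """Base class for all package errors."""


class InputError(FcSerologyError, ValueError):
    """A value violates an operation's domain (range, shape, emptiness)."""


class ConfigurationError(FcSerologyError, ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class DegenerateInputError(InputError):
    """Input is formally valid but makes the quantity undefined
    (zero variance, zero denominator, no comparable sites)."""


class MissingDataError(InputError):
    """A required observation is absent; no imputation is performed."""
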