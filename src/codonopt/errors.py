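"""Exception types shared across the package."""


class CodonOptError(Exception):
    """Base class for all package errors."""


class AlphabetError(CodonOptError, ValueError):
    """A sequence contains a symbol outside the expected alphabet."""


class UsageError(CodonOptError, ValueError):
    """An operation was called with inputs that violate its contract."""
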