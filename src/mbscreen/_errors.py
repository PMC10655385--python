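"""Exception hierarchy shared across the package."""


class MbScreenError(Exception):
    """Base class for all package errors."""


class FormatError(MbScreenError):
    """Input file does not have the expected structure."""


class ValidationError(MbScreenError):
    """Input parsed but violates a domain invariant."""


class ParameterError(MbScreenError):
    """An argument is outside its admissible range."""


class QCError(MbScreenError):
    """A plate fails minimal quality requirements."""


class DegeneratePlateError(MbScreenError):
    """A plate's controls or test-well distribution make scoring undefined."""


class InsufficientDesignError(MbScreenError):
    """Too few distinct doses / dose levels / pairs for the requested fit."""


class PairingError(MbScreenError):
    """Sensitive/resistant results could not be matched."""
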