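"""Exception hierarchy shared by all pipeline stages."""


class EcgDenoiseError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(EcgDenoiseError, ValueError):
    """A caller violated an operation's precondition (lengths, ranges, names)."""


class FormatError(EcgDenoiseError, ValueError):
    """A file did not match the expected schema (missing column, bad header)."""


class ParseError(EcgDenoiseError, ValueError):
    """A cell or field could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateSignalError(EcgDenoiseError, ValueError):
    """A signal is constant / zero-power where variation is required."""


class GateViolationError(EcgDenoiseError, ValueError):
    """A segment with no detectable QRS reached a stage that requires one."""


class DivergenceError(EcgDenoiseError, ArithmeticError):
    """Adaptive filter weights blew up; carries the sample index."""

    def __init__(self, message: str, sample: int | None = None):
        super().__init__(message)
        self.sample = sample


class AlignmentError(EcgDenoiseError, ValueError):
    """RR-interval alignment impossible (fewer than two R peaks)."""


class TrainingError(EcgDenoiseError, ValueError):
    """Classifier training impossible (e.g. a single class in the labels)."""
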