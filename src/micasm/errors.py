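"""Exception hierarchy shared by all micasm modules."""


class MicasmError(Exception):
    """Base class for all errors raised by micasm."""


class ValidationError(MicasmError, ValueError):
    """Invalid argument or inconsistent in-memory data."""


class FormatError(MicasmError, ValueError):
    """A file on disk violates its declared format."""


class DegenerateDataError(MicasmError):
    """A statistic is undefined on the given input.

    Examples: a null distribution with zero spread, a regression with
    fewer than three distinct predictor values, or a slope fit on points
    with zero variance.
    """
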