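"""Exception hierarchy for lnpkit."""


class LnpkitError(Exception):
    """Base class for all lnpkit errors."""


class InvalidInputError(LnpkitError, ValueError):
    """A physical parameter or array violates its documented domain."""


class ParseError(LnpkitError, ValueError):
    """A text input file could not be parsed; message carries the line number."""


class TypingError(ParseError):
    """Molecule typing could not be resolved for a coordinate file."""


class SelectionError(LnpkitError, ValueError):
    """An atom selection is empty or inconsistent (e.g. donor without H)."""


class InsufficientDataError(LnpkitError, ValueError):
    """Too few data points for the requested fit or statistic."""


class DataQualityError(LnpkitError, ValueError):
    """Data fail a quality gate (e.g. widespread negative intensities)."""


class FitFailureError(LnpkitError, RuntimeError):
    """An optimisation failed to converge; carries the last iterate."""

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class PorodInvalidError(LnpkitError, ValueError):
    """Fitted Porod constant is not positive: wrong window or no sharp interface."""


class ExtrapolationError(LnpkitError, ValueError):
    """Splice mismatch between measured curve and analytic extrapolation."""


class GenerationError(LnpkitError, ValueError):
    """A synthetic-data request cannot be satisfied."""
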