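"""Exception hierarchy.

Input/configuration problems raise :class:`InputError` subclasses (CLI exit
code 2); numerical failures raise :class:`NumericalError` subclasses (exit 3).
"""


class HifsigError(Exception):
    """Base class for all package errors."""


class InputError(HifsigError):
    """Invalid user input: bad shapes, missing columns, out-of-range values."""


class ConfigError(InputError):
    """Invalid configuration object; the message names the offending field."""


class MissingGeneError(InputError):
    """A requested gene symbol is absent from the expression matrix."""

    def __init__(self, symbols):
        self.symbols = sorted(symbols) if not isinstance(symbols, str) else [symbols]
        super().__init__(f"gene symbol(s) not in matrix: {', '.join(self.symbols)}")


class UndefinedCorrelationError(InputError):
    """Correlation requested against a zero-variance vector."""


class ZeroAreaError(InputError):
    """A mask selects no pixels."""


class DegenerateScoreError(InputError):
    """All samples share one score value; a median split is impossible."""


class NumericalError(HifsigError):
    """A computation failed numerically (non-convergence, unfittable model)."""


class UnfitError(NumericalError):
    """A survival model cannot be fitted (e.g. no observed events)."""


class AlignmentError(NumericalError):
    """Image registration failed: correlation peak below the floor."""
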