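"""Exception and warning types shared across the pipeline.

Undefined statistics (no germinated seed, a zero control mean, ...) are not
programming errors: by default they propagate as NaN with a
:class:`UndefinedStatisticWarning`, and only raise when a caller asks for
``strict=True``.
"""

from __future__ import annotations

import warnings


class GermQtlError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GermQtlError, ValueError):
    """Input violates a documented precondition (negative count, r >= 0.5, ...)."""


class InvalidDesignError(GermQtlError, ValueError):
    """Unbalanced or degenerate experimental design."""


class UndefinedStatisticError(GermQtlError, ArithmeticError):
    """A statistic is mathematically undefined for this input (strict mode)."""


class ParseError(GermQtlError, ValueError):
    """Malformed delimited input; carries the offending line number when known."""


class UndefinedStatisticWarning(UserWarning):
    """Emitted when an undefined statistic is reported as missing (NaN)."""


class DataWarning(UserWarning):
    """Non-fatal data issue: dropped column, missing treatment partner, ties ..."""


def undefined(message: str, strict: bool) -> float:
    """Handle an undefined statistic: raise in strict mode, else warn and NaN."""
    if strict:
        raise UndefinedStatisticError(message)
    warnings.warn(message, UndefinedStatisticWarning, stacklevel=3)
    return float("nan")
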