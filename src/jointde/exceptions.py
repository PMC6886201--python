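"""Typed errors raised by jointde.

The CLI maps these onto exit codes: ValidationError -> 3,
NumericalError -> 4, anything argparse-level -> 2.
"""


class JointDEError(Exception):
    """Base class for all jointde errors."""


class ValidationError(JointDEError, ValueError):
    """Malformed or inconsistent user input (tables, configs, shapes)."""


class NumericalError(JointDEError, ArithmeticError):
    """A computation could not be carried out (rank deficiency, etc.)."""


class UnidentifiableError(NumericalError):
    """The centered design matrix is rank deficient, so per-gene OLS
    coefficients (and hence the whole joint fit) are not identifiable."""
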