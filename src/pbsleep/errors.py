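"""Exception hierarchy shared across the package.

The command-line interface maps these onto distinct exit codes
(parse = 3, validation = 4, computation = 5).
"""


class PbsleepError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PbsleepError, ValueError):
    """A delimited input file could not be parsed (bad cell, empty file...)."""


class InvalidInputError(PbsleepError, ValueError):
    """Input data violates a precondition (e.g. all-zero signal, window too long)."""


class InvalidParameterError(PbsleepError, ValueError):
    """A parameter value is out of its valid range (e.g. th_abs >= th_di)."""


class ComputationError(PbsleepError, RuntimeError):
    """A numeric step failed in a way that is not an input/parameter problem."""


class IntegrityError(PbsleepError):
    """A packaged fixture does not match its recorded checksum."""
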