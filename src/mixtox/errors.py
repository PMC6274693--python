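"""Exception hierarchy for mixtox."""


class MixtoxError(Exception):
    """Base class for all package errors."""


class ParseError(MixtoxError, ValueError):
    """Malformed input text (SMILES, ratio strings, CSV cells)."""


class DataLoadError(MixtoxError, ValueError):
    """Structurally invalid table: missing columns, duplicate ids, broken references."""


class DescriptorError(MixtoxError, ValueError):
    """A molecular descriptor is undefined or unconfigurable for the given molecule."""


class ValidationError(MixtoxError, ValueError):
    """Violated numeric precondition (fraction sums, vector lengths, ...)."""


class FitError(MixtoxError, ValueError):
    """Model fitting failed: singular design, too few samples, bad hyperparameters."""


class UndefinedStatisticError(MixtoxError, ZeroDivisionError):
    """A statistic's defining formula divides by zero (zero variance, |r| >= 1, ...)."""
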