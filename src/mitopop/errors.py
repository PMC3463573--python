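"""Exception hierarchy shared across the package."""


class MitopopError(Exception):
    """Base class for all package-specific errors."""


class InputError(MitopopError, ValueError):
    """Malformed or empty user input (files, tables, option values)."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (ragged lengths, bad symbols)."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the statistic is undefined (e.g. zero retained sites)."""


class UndefinedStatisticError(MitopopError, ArithmeticError):
    """Statistic has no defined value for this sample (e.g. Tajima's D with S = 0)."""


class DomainError(MitopopError, ValueError):
    """Parameter outside the mathematical domain of a formula."""


class CodonError(DomainError):
    """Stop codon or ambiguous base where a sense codon is required."""


class FrameError(InputError):
    """Reading frame inconsistent with the data (internal stop codons)."""


class FitError(MitopopError, RuntimeError):
    """Optimisation failed to converge from every start point."""


class OverflowStatisticError(UndefinedStatisticError):
    """Probability underflow/overflow makes a log-odds statistic non-finite."""


class SizeError(MitopopError, ValueError):
    """Problem size exceeds an exhaustive-search guard."""


class ConfigError(InputError):
    """Invalid pipeline configuration."""
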