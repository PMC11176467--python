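"""Exception hierarchy for mrmediate.

All package-specific failures derive from :class:`MRMediateError` so callers
(and the CLI) can distinguish user-input problems from genuine bugs.
"""


class MRMediateError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(MRMediateError):
    """A configuration, column mapping, or study file is invalid."""


class EmptyInputError(MRMediateError):
    """An input table or instrument set contains no usable rows."""


class HarmonizationError(MRMediateError):
    """Allele harmonization cannot proceed (e.g. duplicated SNP ids)."""


class UndefinedRatioError(MRMediateError):
    """A Wald ratio is requested with a zero exposure effect."""


class InsufficientInstrumentsError(MRMediateError):
    """Fewer instruments than the method's minimum are available."""


class DegenerateWeightsError(MRMediateError):
    """All instrument weights collapsed to zero (e.g. after penalization)."""


class ConvergenceError(MRMediateError):
    """An iterative optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
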