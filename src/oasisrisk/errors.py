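"""Exception hierarchy shared across the pipeline."""


class OasisRiskError(Exception):
    """Base class for all package errors."""


class FormatError(OasisRiskError):
    """A file does not match the expected schema or dialect."""


class ValidationError(OasisRiskError):
    """Input data violates a domain invariant."""


class AlignmentError(OasisRiskError):
    """Raster layers do not share grid shape/transform."""


class ConfigurationError(OasisRiskError):
    """An option keyword or parameter value is not recognised."""


class UndefinedStatisticError(OasisRiskError):
    """A statistic is requested on data where it is undefined (e.g. empty survey)."""


class AnalysisError(OasisRiskError):
    """A statistical analysis cannot be run on the given groups."""


class ConvergenceError(OasisRiskError):
    """An iterative fit failed to converge within its iteration budget."""
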