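"""Exception hierarchy for the mirtlda pipeline."""


class MirTldaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MirTldaError):
    """Input file columns/layout cannot be resolved."""


class IntegrityError(MirTldaError):
    """Duplicate or inconsistent records in an input table."""


class CtParseError(MirTldaError):
    """A CT cell is neither numeric nor the undetermined token."""


class ValidationError(MirTldaError):
    """Annotation or configuration values outside their allowed sets."""


class NormalizationError(MirTldaError):
    """Endogenous-control aggregation or calibrator lookup failed."""


class LayoutError(MirTldaError):
    """Unknown result-table layout id."""


class FitError(MirTldaError):
    """A model fit (e.g. the variance-prior fit) did not converge."""
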