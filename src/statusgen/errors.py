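"""Exception types shared across the package."""


class StatusgenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StatusgenError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class InfeasibleTargetError(StatusgenError, ValueError):
    """A requested calibration target cannot be reached, e.g. a PGS
    incremental R-squared above the squared latent-score/phenotype
    correlation."""


class FormatError(StatusgenError, ValueError):
    """An input file violates its documented schema."""


class DegenerateInputError(StatusgenError, ValueError):
    """Input data make the requested estimate undefined (zero variance,
    no adoptees, collinear regressors, ...)."""
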