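"""Exception hierarchy shared across the package."""


class NanodomainError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(NanodomainError):
    """Input carries no usable signal (zero-mean trace, flat image, ...)."""


class InsufficientDataError(NanodomainError):
    """Not enough data points/curves/molecules for the requested analysis."""


class IncompatibleTracesError(NanodomainError):
    """Traces do not share the same bin grid or duration."""


class NonNormalizableError(NanodomainError):
    """Correlation amplitude at the reference lag is not positive."""


class InvalidConfigError(NanodomainError):
    """Simulation or clustering configuration violates its invariants."""


class FitFailureError(NanodomainError):
    """Nonlinear least squares did not converge to a usable solution."""


class DegenerateRegressionError(NanodomainError):
    """Regression abscissae carry no variance."""


class InvalidRoiError(NanodomainError):
    """Region of interest has zero or negative area."""


class ClusterFailureError(NanodomainError):
    """DP-means did not reach a stable assignment within the iteration cap."""
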