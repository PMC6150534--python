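"""Exception hierarchy shared across the package."""


class NetcogError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NetcogError):
    """An invalid simulation or pipeline configuration field."""


class FormatError(NetcogError):
    """A malformed input file (shape mismatch, bad label code, non-numeric cell)."""


class DegenerateInputError(NetcogError):
    """Input without enough structure for the requested computation
    (rank-deficient task matrix, empty component, collinear covariates...)."""


class EmptyNetworkError(NetcogError):
    """A network subset request matched no vertices."""


class InsufficientDataError(NetcogError):
    """Too few observations for the requested statistic."""


class InstabilityError(NetcogError):
    """The bootstrap statistic failed on more than the tolerated share of resamples."""


class PipelineError(NetcogError):
    """A pipeline stage failed; carries the stage name and partial output inventory."""

    def __init__(self, stage: str, message: str, inventory=None):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.inventory = list(inventory or [])
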