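"""Exception types raised across the package."""


class MbdivError(Exception):
    """Base class for package errors."""


class FormatError(MbdivError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(MbdivError):
    """Input data violate a domain invariant (e.g. ts <= te)."""


class DegenerateCovariateError(MbdivError):
    """A covariate trajectory is constant and carries no information."""


class SimulationError(MbdivError):
    """Forward simulation failed (e.g. attempt cap exceeded)."""


class InitializationError(MbdivError):
    """The MCMC starting state has zero posterior probability."""


class DegenerateChainWarning(UserWarning):
    """An MCMC trace has zero variance; diagnostics are not meaningful."""
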